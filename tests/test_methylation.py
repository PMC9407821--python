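import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from convergeomics import methylation
from convergeomics.exceptions import AnalysisError
from convergeomics.io import Gene, GenomeAnnotation
from conftest import make_report
from oracles import context_oracle, revcomp_oracle


class TestClassifyContext:
    def test_plus_strand_definitions(self):
        genome = {"c": "ACGATCAGTACATT"}
        assert methylation.classify_context(genome, "c", 1, "+") == "CG"   # CGA
        assert methylation.classify_context(genome, "c", 5, "+") == "CHG"  # CAG
        assert methylation.classify_context(genome, "c", 10, "+") == "CHH"  # CAT

    def test_non_cytosine_rejected(self):
        with pytest.raises(ValueError, match="not C"):
            methylation.classify_context({"c": "AAA"}, "c", 0, "+")

    def test_all_64_triplets_against_reverse_complement_oracle(self):
        # plus strand: direct triplet; minus strand: the site is a G on the
        # reference and its context is the reverse complement read 5'->3'
        for triplet in map("".join, itertools.product("ACGT", repeat=3)):
            plus_seq = "AA" + "C" + triplet[1:] + "AA"
            if triplet[0] == "C":
                assert (
                    methylation.classify_context({"c": plus_seq}, "c", 2, "+")
                    == context_oracle("C" + triplet[1:])
                )
            minus_seq = "AA" + revcomp_oracle("C" + triplet[1:]) + "AA"
            # the C of the minus-strand site maps to the G at index 4
            assert (
                methylation.classify_context({"c": minus_seq}, "c", 4, "-")
                == context_oracle("C" + triplet[1:])
            )

    def test_chromosome_end_defaults_to_chh(self):
        assert methylation.classify_context({"c": "AAC"}, "c", 2, "+") == "CHH"
        assert methylation.classify_context({"c": "ACA"}, "c", 1, "+") == "CHH"

    def test_vectorized_site_discovery_agrees_with_scalar(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        from convergeomics._seq import cytosine_sites

        pos, strand, ctx = cytosine_sites(seq)
        genome = {"c": seq}
        for p, s, c in zip(pos, strand, ctx):
            assert methylation.classify_context(genome, "c", int(p), str(s)) == c


class TestSiteAndBinLevels:
    def test_site_level_values(self):
        assert methylation.site_level(3, 1) == 0.75
        assert methylation.site_level(0, 5) == 0.0
        assert methylation.site_level(7, 0) == 1.0
        with pytest.raises(AnalysisError):
            methylation.site_level(0, 0)

    def test_bin_pools_reads_not_site_levels(self):
        rep = make_report(
            [("c", 100, "+", "CG", 3, 1), ("c", 200, "+", "CG", 1, 3),
             ("c", 300, "+", "CG", 9, 1), ("c", 400, "+", "CG", 0, 1)]
        )
        bins = methylation.bin_levels(rep, bin_size=250, context="CG")
        # first bin pools (3+1)/(4+4) = 0.5
        assert bins.loc[bins["bin_start"] == 0, "level"].iloc[0] == 0.5
        # second bin pools 9/11, NOT the mean of levels (0.45)
        assert bins.loc[bins["bin_start"] == 250, "level"].iloc[0] == pytest.approx(9 / 11)

    def test_empty_bins_absent(self):
        rep = make_report([("c", 25_000, "+", "CG", 1, 1)])
        bins = methylation.bin_levels(rep, bin_size=10_000)
        assert list(bins["bin_start"]) == [20_000]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 20), st.integers(0, 20)).filter(lambda t: sum(t) > 0),
            min_size=1,
            max_size=30,
        ),
        st.data(),
    )
    def test_pooled_level_partition_identity(self, sites, data):
        """Pooled level over all sites equals the coverage-weighted mean of
        the pooled levels of any partition of the sites."""
        cut = data.draw(st.integers(0, len(sites)))
        mc = sum(m for m, _ in sites)
        cov = sum(m + u for m, u in sites)
        parts = [sites[:cut], sites[cut:]]
        weighted = sum(
            sum(m for m, _ in part)  # part pooled level * part coverage
            for part in parts
            if part
        )
        assert mc / cov == weighted / cov  # exact integer arithmetic


class TestCoverageSummary:
    def test_coverage_strata_counts(self):
        rep = make_report(
            [("c", i, "+", "CG", m, u) for i, (m, u) in enumerate([(1, 0), (2, 2), (5, 0), (0, 9)])]
        )
        out = methylation.coverage_summary(rep)
        assert out["CG"]["n_cov1"] == 4
        assert out["CG"]["n_cov5"] == 2
        # of the two >=5 sites, one (5/5) exceeds level 0.5
        assert out["CG"]["frac_gt50_cov5"] == 0.5

    def test_all_unmethylated_fraction_zero(self):
        rep = make_report([("c", i, "+", "CHH", 0, 6) for i in range(5)])
        assert methylation.coverage_summary(rep)["CHH"]["frac_gt50_cov5"] == 0.0


class TestElementLevels:
    def test_single_gene_toy_arithmetic(self):
        gene = Gene(gene_id="g", chrom="c", strand="+", start=2000, end=3000,
                    exons=((2000, 2400), (2600, 3000)))
        ann = GenomeAnnotation(genes=[gene])
        rep = make_report(
            [("c", 1500, "+", "CG", 1, 9),   # promoter [1000,2000)
             ("c", 2200, "+", "CG", 8, 2)]   # body (exon 1)
        )
        levels = methylation.element_levels(rep, ann)
        assert levels["promoter"] == pytest.approx(0.1)
        assert levels["gene"] == pytest.approx(0.8)
        assert levels["exon"] == pytest.approx(0.8)
        assert np.isnan(levels["intron"])  # no covered CG in the intron

    def test_promoter_trough_lower_than_body(self, small_config):
        from convergeomics.simulate import simulate_genome_and_annotation, simulate_methylome

        genome, ann = simulate_genome_and_annotation(small_config)
        reports, _ = simulate_methylome(small_config, genome, ann)
        for rep in reports.values():
            levels = methylation.element_levels(rep, ann)
            assert levels["promoter"] < levels["gene"]


class TestMetageneProfile:
    def _uniform_report(self, ann, rng, level=0.8, spacing=37):
        rows = []
        chrom_len = ann.chrom_sizes["c"]
        for pos in range(0, chrom_len, spacing):
            cov = 10
            mc = rng.binomial(cov, level)
            rows.append(("c", pos, "+", "CG", mc, cov - mc))
        return make_report(rows)

    def _annotation(self, n=12, body=2000):
        genes = []
        cursor = 2500
        for i in range(n):
            strand = "+" if i % 2 == 0 else "-"
            genes.append(
                Gene(gene_id=f"g{i}", chrom="c", strand=strand, start=cursor,
                     end=cursor + body, exons=((cursor, cursor + body),))
            )
            cursor += body + 5000
        return GenomeAnnotation(genes=genes, chrom_sizes={"c": cursor + 2500})

    def test_body_bins_are_100bp_for_2kb_gene(self):
        # gene length 2000 with 20 bins -> each body bin spans 100 bp; check
        # by placing one site per 100 bp stripe with a distinct level
        ann = GenomeAnnotation(
            genes=[Gene(gene_id="g", chrom="c", strand="+", start=2000, end=4000,
                        exons=((2000, 4000),))],
            chrom_sizes={"c": 10000},
        )
        rows = [("c", 2000 + 100 * b + 50, "+", "CG", b, 20 - b) for b in range(20)]
        profile = methylation.metagene_profile(make_report(rows), ann)
        body = profile[20:40]
        assert np.allclose(body, np.arange(20) / 20)

    def test_uniform_methylome_is_flat(self):
        rng = np.random.default_rng(1)
        ann = self._annotation()
        profile = methylation.metagene_profile(self._uniform_report(ann, rng), ann)
        assert np.nanmax(profile) - np.nanmin(profile) < 0.15

    def test_promoter_trough_minimum_near_tss(self, small_config):
        from convergeomics.simulate import simulate_genome_and_annotation, simulate_methylome

        genome, ann = simulate_genome_and_annotation(small_config)
        reports, _ = simulate_methylome(small_config, genome, ann)
        profile = methylation.metagene_profile(next(iter(reports.values())), ann)
        assert 15 <= int(np.nanargmin(profile)) <= 25

    def test_reverse_complement_mirror_invariance(self):
        """Reverse-complementing the assembly (mirroring coordinates and
        strands) must leave the metagene profile unchanged."""
        rng = np.random.default_rng(2)
        ann = self._annotation(n=6)
        chrom_len = ann.chrom_sizes["c"]
        rows = []
        for pos in range(0, chrom_len, 23):
            level = 0.2 + 0.6 * ((pos // 1000) % 2)
            cov = 8
            mc = rng.binomial(cov, level)
            rows.append(("c", pos, "+", "CG", mc, cov - mc))
        rep = make_report(rows)
        profile = methylation.metagene_profile(rep, ann)

        mirrored_rows = [
            ("c", chrom_len - 1 - pos, "-", "CG", mc, uc)
            for (_, pos, _, _, mc, uc) in rows
        ]
        mirrored_genes = [
            Gene(
                gene_id=g.gene_id, chrom="c",
                strand="-" if g.strand == "+" else "+",
                start=chrom_len - g.end, end=chrom_len - g.start,
                exons=tuple(sorted((chrom_len - e, chrom_len - s) for s, e in g.exons)),
            )
            for g in ann
        ]
        mirrored_ann = GenomeAnnotation(genes=mirrored_genes, chrom_sizes={"c": chrom_len})
        mirrored = methylation.metagene_profile(make_report(mirrored_rows), mirrored_ann)
        np.testing.assert_allclose(profile, mirrored, atol=1e-12)
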