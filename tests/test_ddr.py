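"""The repeat clock itself: d_DR values, criteria gating, ranking."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from ddrclock import datasets
from ddrclock.ddr import (
    CriterionError,
    DdrResult,
    analyze_family,
    check_criterion2,
    compute_ddr,
    criterion2_permutation,
    rank_table,
    reference_distances,
)
from ddrclock.distances import as_model
from ddrclock.repeatio import (
    AlignmentSet,
    RepeatPair,
    SeqRecordNT,
    build_repeat_pair,
)
from ddrclock.simulate import SimConfig, simulate_family, star_tree


def _pair(first: str, second: str, gene="g", species="sp") -> RepeatPair:
    return build_repeat_pair(
        gene, species, "unknown",
        SeqRecordNT(f"{gene}_1", first), SeqRecordNT(f"{gene}_2", second),
    )


class TestComputeDdr:
    def test_identical_repeats_are_the_ea_gene(self):
        """The zero point: identical repeat copies give d_DR = 0."""
        for model in ("p", "jc69", "k2p", "tn93", "mcl_composite"):
            res = compute_ddr(_pair("ACGTACGTAC", "ACGTACGTAC"), model)
            assert res.ddr == 0.0
            assert res.identity_pct == 100.0

    def test_simulated_divergence_is_recovered(self):
        """Per-copy divergence 0.25 -> expected d_DR of 0.5."""
        res = simulate_family(
            SimConfig(
                seed=21, repeat_length=10_000, n_species=2,
                mu_t=0.25, stem_offset=0.0,
            )
        )
        out = compute_ddr(res.pairs[0], "jc69")
        assert out.ddr == pytest.approx(0.5, abs=0.05)

    def test_saturated_pair_is_flagged(self):
        a = "ACGT" * 25
        b = "CATG" * 25  # every site differs, way past jc69 saturation
        res = compute_ddr(_pair(a, b), "jc69")
        assert res.saturated
        assert not res.passes_criteria


class TestCriterion2:
    @pytest.mark.parametrize(
        "identity, threshold, expected",
        [(32.6, 30.0, True), (61.5, 30.0, True), (25.0, 30.0, False),
         (29.9, 30.0, False), (30.0, 30.0, True)],
    )
    def test_threshold_rule(self, identity, threshold, expected):
        assert check_criterion2(identity, threshold) is expected

    def test_threshold_must_exceed_random_floor(self):
        with pytest.raises(CriterionError):
            check_criterion2(50.0, 25.0)
        with pytest.raises(CriterionError):
            check_criterion2(50.0, 101.0)

    def test_permutation_mode_rejects_random_pairs(self, rng):
        """Unrelated random sequences should essentially never pass."""
        passes = 0
        trials = 60
        for t in range(trials):
            a = "".join(rng.choice(list("ACGT"), 300))
            b = "".join(rng.choice(list("ACGT"), 300))
            passes += criterion2_permutation(
                _pair(a, b), replicates=99, seed=t
            )
        assert passes <= 3  # ~1% expected pass rate at the 99th percentile

    def test_permutation_mode_accepts_conserved_pairs(self):
        res = simulate_family(
            SimConfig(seed=9, repeat_length=300, n_species=2, mu_t=0.2)
        )
        assert criterion2_permutation(res.pairs[0], replicates=99, seed=0)


class TestRankTable:
    @staticmethod
    def _results_from_fixture(family: str) -> list[DdrResult]:
        df = datasets.load_repeat_table(family)
        return [
            DdrResult(
                gene_id=f"{family}_{row.species}",
                species=row.species,
                domain=row.domain,
                identical=row.identical,
                compared=row.compared,
                identity_pct=row.identity_pct,
                ddr=row.ddr,
                model=as_model("mcl_composite"),
            )
            for row in df.itertuples()
        ]

    def test_tbp_minimum_is_mj(self):
        table = rank_table(self._results_from_fixture("tbp"), family="tbp")
        assert table.results[0].species == "Mj"
        assert table.results[0].ddr == 0.488

    def test_tfiib_minimum_is_mm(self):
        table = rank_table(self._results_from_fixture("tfiib"), family="tfiib")
        assert table.results[0].species == "Mm"
        assert table.results[0].ddr == 0.784

    def test_domain_summary_orders_archaea_below_eukaryotes(self):
        """Archaeal d_DR ranges sit below eukaryotic ones in both families."""
        for family in ("tbp", "tfiib"):
            table = rank_table(self._results_from_fixture(family), family=family)
            summary = table.domain_summary()
            assert summary["euryarchaeota"][0] < summary["eukaryote"][0]
            assert summary["euryarchaeota"][1] < summary["eukaryote"][1]

    def test_single_entry(self):
        only = self._results_from_fixture("tbp")[:1]
        assert rank_table(only).results == only

    def test_mixed_models_rejected(self):
        import dataclasses
        results = self._results_from_fixture("tbp")[:2]
        results[1] = dataclasses.replace(results[1], model=as_model("jc69"))
        with pytest.raises(ValueError, match="mixed"):
            rank_table(results)

    def test_criterion_failures_are_flagged_not_dropped(self):
        import dataclasses
        results = self._results_from_fixture("tbp")[:5]
        results[0] = dataclasses.replace(
            results[0], criterion2_pass=False
        )
        table = rank_table(results)
        assert len(table.results) == 4
        assert len(table.excluded) == 1
        assert table.excluded[0].species == results[0].species
        rows = table.to_rows()
        assert sum(not r["ranked"] for r in rows) == 1

    def test_write_tsv(self, tmp_path):
        table = rank_table(self._results_from_fixture("tbp"), family="tbp")
        out = tmp_path / "table.tsv"
        table.write_tsv(out, provenance="test-run")
        lines = out.read_text().splitlines()
        assert lines[0] == "# test-run"
        assert len(lines) == 2 + 1 + 34  # provenance, family, header, rows


class TestAnalyzeFamily:
    def test_full_pipeline_on_simulated_family(self, simulated_family):
        table = analyze_family(
            simulated_family.pairs, "jc69", family="sim"
        )
        assert len(table.results) == len(simulated_family.pairs)
        c1 = table.results[0].criterion1
        assert c1 is not None and c1.passed
        # estimates track the (equal) generating truth
        truth = simulated_family.true_ddr
        for res in table.results:
            assert res.ddr == pytest.approx(truth[res.species], abs=0.12)

    def test_ranking_invariant_across_models(self):
        """jc/k2p/tn93 rank simulated genes almost identically."""
        tree = star_tree(30, 0.0)
        rng = np.random.default_rng(17)
        for tip in tree.tips():
            tip.length = float(rng.uniform(0.05, 0.45))
        res = simulate_family(
            SimConfig(
                seed=17, repeat_length=3000, species_tree=tree,
                stem_offset=0.05,
            )
        )
        tables = {
            m: analyze_family(res.pairs, m, family="sim", run_criterion1=False)
            for m in ("jc69", "k2p", "tn93")
        }
        ranks = {
            m: [r.species for r in t.results] for m, t in tables.items()
        }
        order = {m: {sp: i for i, sp in enumerate(v)} for m, v in ranks.items()}
        species = ranks["jc69"]
        for other in ("k2p", "tn93"):
            rho = sps.spearmanr(
                [order["jc69"][s] for s in species],
                [order[other][s] for s in species],
            ).statistic
            assert rho >= 0.95


class TestReferenceDistances:
    def test_self_distance_zero_and_consistency(self):
        from ddrclock.distances import distance
        seqs = ["ACGTACGTACGT", "ACGAACGTACTT", "ACGTACGGACGA"]
        aln = AlignmentSet(
            [SeqRecordNT(f"s{i}", s) for i, s in enumerate(seqs)]
        )
        ref = reference_distances(aln, "s0", "jc69")
        assert ref.distances["s0"] == 0.0
        assert ref.distances["s1"] == pytest.approx(
            distance(seqs[0], seqs[1], "jc69")
        )

    def test_missing_reference(self):
        aln = AlignmentSet([SeqRecordNT("a", "ACGT"), SeqRecordNT("b", "ACGT")])
        with pytest.raises(KeyError):
            reference_distances(aln, "zz", "p")

    def test_star_tree_reference_distances_near_2t(self):
        """All tips at depth t from the center: every d_ref ~ 2t."""
        res = simulate_family(
            SimConfig(
                seed=31, repeat_length=8000, n_species=5,
                mu_t=0.2, stem_offset=0.0,
            )
        )
        firsts = AlignmentSet(
            [SeqRecordNT(p.species, p.first.seq) for p in res.pairs]
        )
        ref = reference_distances(firsts, "s1", "jc69")
        for sp, d in ref.distances.items():
            if sp != "s1":
                assert d == pytest.approx(0.4, abs=0.05)
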