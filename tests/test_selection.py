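"""Feature selectors: rSNR, two-class SNR, Welch's t, random and link-based."""

import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rsnr.errors import ConsistencyError, UndefinedScoreError
from rsnr.profiles import InteractionSet
from rsnr.selection import (GeneRanking, build_split, random_selection,
                            rsnr_ranking, rsnr_scores, select_section,
                            select_top, snr_c_scores, string_gene_selection,
                            string_link_selection, welch_t_scores)
from rsnr.simulate import atgenexpress_config, default_config, generate

from conftest import build_dataset


# -- scalar-loop oracles (kept deliberately independent of the vectorized path)


def rsnr_scalar(ds, split, gene):
    pos = [float(ds.values.loc[gene, s]) for s in split.positive_samples]
    mu_p, sd_p = statistics.fmean(pos), statistics.stdev(pos)
    cond_means = [statistics.fmean(float(ds.values.loc[gene, s]) for s in ids)
                  for ids in split.negative_samples.values()]
    mu_n, sd_n = statistics.fmean(cond_means), statistics.stdev(cond_means)
    if sd_p == 0:
        return float("inf") if sd_n > 0 else 0.0
    if sd_n == 0:
        return 0.0
    snr_p, snr_n = abs(mu_p) / sd_p, abs(mu_n) / sd_n
    if snr_n == 0:
        return float("inf") if snr_p > 0 else 0.0
    return snr_p / snr_n


def snr_c_scalar(ds, c1, c2, gene):
    a = [float(ds.values.loc[gene, s]) for s in c1]
    b = [float(ds.values.loc[gene, s]) for s in c2]
    denom = statistics.stdev(a) + statistics.stdev(b)
    num = abs(statistics.fmean(a) - statistics.fmean(b))
    if denom == 0:
        return 0.0 if num == 0 else float("inf")
    return num / denom


def welch_scalar(ds, c1, c2, gene):
    a = [float(ds.values.loc[gene, s]) for s in c1]
    b = [float(ds.values.loc[gene, s]) for s in c2]
    denom = (statistics.variance(a) / len(a) + statistics.variance(b) / len(b)) ** 0.5
    num = abs(statistics.fmean(a) - statistics.fmean(b))
    if denom == 0:
        return 0.0 if num == 0 else float("inf")
    return num / denom


def _multi_condition_ds(cond_values: dict, factors: dict | None = None):
    """cond_values: condition -> gene -> list of sample values (one tp each)."""
    meta, values = [], {}
    genes = sorted(next(iter(cond_values.values())))
    for g in genes:
        values[g] = []
    for cid in sorted(cond_values):
        fac = (factors or {}).get(cid, f"f_{cid}")
        n = len(cond_values[cid][genes[0]])
        for j in range(n):
            meta.append((f"{cid}_s{j}", cid, fac, float(j), 1))
        for g in genes:
            values[g].extend(cond_values[cid][g])
    return build_dataset(values, meta)


class TestBuildSplit:
    def test_single_factor_disjointness(self):
        ds = _multi_condition_ds({c: {"g1": [1.0, 2.0]} for c in ("A", "B", "C")})
        split = build_split(ds, None, "A")
        assert set(split.negative_conditions) == {"B", "C"}
        assert split.excluded_conditions == ()

    def test_shared_factor_conditions_are_excluded(self):
        ds, _ = generate(atgenexpress_config(n_genes=10, n_planted_per_condition=0))
        target = "cold-root"
        split = build_split(ds, None, target)
        # negative set: conditions involving neither "cold" nor "root"
        assert len(split.negative_conditions) == 8  # 8 other treatments x shoot
        for cid in split.negative_conditions:
            assert not (ds.conditions[cid].factors & {"cold", "root"})
        for cid in split.excluded_conditions:
            assert ds.conditions[cid].factors & {"cold", "root"}

    def test_empty_negative_set_is_an_error(self):
        ds = _multi_condition_ds(
            {c: {"g1": [1.0, 2.0]} for c in ("A", "B")},
            factors={"A": "shared;x", "B": "shared;y"})
        with pytest.raises(UndefinedScoreError, match="negative set is empty"):
            build_split(ds, None, "A")

    def test_respects_training_mask(self):
        ds = _multi_condition_ds({c: {"g1": [1.0, 2.0]} for c in ("A", "B", "C")})
        mask = [s for s in ds.sample_ids if not s.startswith("C")]
        split = build_split(ds, mask, "A")
        assert set(split.negative_conditions) == {"B"}


class TestRsnrScores:
    def test_hand_computed_example(self):
        # positive values [9,10,11,10]: mu=10, sd=sqrt(2/3) -> SNR_pos ~ 12.2474
        # negative condition means [5,10,15]: mu=10, sd=5 -> SNR_neg = 2
        ds = _multi_condition_ds({
            "pos": {"g1": [9.0, 10.0, 11.0, 10.0]},
            "n1": {"g1": [5.0, 5.0]},
            "n2": {"g1": [10.0, 10.0]},
            "n3": {"g1": [15.0, 15.0]},
        })
        comp = rsnr_scores(ds, build_split(ds, None, "pos"))
        row = comp.loc["g1"]
        assert row["snr_pos"] == pytest.approx(10 / np.sqrt(2 / 3), rel=1e-12)
        assert row["snr_neg"] == pytest.approx(2.0, rel=1e-12)
        assert row["rsnr"] == pytest.approx(6.123724356957945, rel=1e-10)

    def test_constant_positive_gene_gets_infinity_and_top_rank(self):
        ds = _multi_condition_ds({
            "pos": {"g1": [7.0, 7.0, 7.0], "g2": [5.0, 9.0, 7.0]},
            "n1": {"g1": [5.0, 5.0], "g2": [6.0, 6.0]},
            "n2": {"g1": [9.0, 9.0], "g2": [8.0, 8.0]},
        })
        ranking = rsnr_ranking(ds, "pos")
        assert np.isinf(ranking.scores[0]) and ranking.genes[0] == "g1"

    def test_no_cross_condition_variation_scores_zero(self):
        ds = _multi_condition_ds({
            "pos": {"g1": [6.0, 8.0]},
            "n1": {"g1": [7.0, 7.0]},
            "n2": {"g1": [7.0, 7.0]},
        })
        comp = rsnr_scores(ds, build_split(ds, None, "pos"))
        assert comp.loc["g1", "rsnr"] == 0.0

    def test_cv_quotient_identity(self, small_planted):
        ds, _ = small_planted
        for cid in list(ds.conditions)[:2]:
            comp = rsnr_scores(ds, build_split(ds, None, cid))
            finite = np.isfinite(comp["rsnr"]) & (comp["rsnr"] > 0)
            cv_pos = comp["sigma_pos"] / comp["mu_pos"].abs()
            cv_neg = comp["sigma_neg"] / comp["mu_neg"].abs()
            np.testing.assert_allclose(comp.loc[finite, "rsnr"],
                                       (cv_neg / cv_pos)[finite], atol=1e-10)

    def test_matches_scalar_loop_oracle(self, rng):
        ds, _ = generate(default_config(n_genes=30, n_planted_per_condition=2,
                                        n_timepoints=3, seed=21))
        split = build_split(ds, None, sorted(ds.conditions)[0])
        comp = rsnr_scores(ds, split)
        for g in ds.genes:
            assert comp.loc[g, "rsnr"] == pytest.approx(rsnr_scalar(ds, split, g),
                                                        rel=1e-10)

    def test_per_timepoint_aggregation_differs_but_ranks_planted_high(self):
        ds, truth = generate(default_config(n_genes=120, n_planted_per_condition=5,
                                            seed=3))
        cid = sorted(ds.conditions)[0]
        split = build_split(ds, None, cid)
        pooled = rsnr_scores(ds, split, aggregation="pooled")
        per_tp = rsnr_scores(ds, split, aggregation="per_timepoint")
        assert not np.allclose(pooled["rsnr"], per_tp["rsnr"])
        ranking = GeneRanking.from_scores(cid, "rsnr", ds.genes,
                                          per_tp["rsnr"].to_numpy())
        top = set(ranking.top(5))
        assert len(top & truth.planted_set(cid)) >= 4


class TestTwoClassScores:
    def _two_class_ds(self):
        # per-gene deviations (+r, +r, -r, -r) with r = sqrt(3) give a sample
        # (n-1) standard deviation of exactly 2 at n = 4
        r = np.sqrt(3.0)
        return _multi_condition_ds({
            "c1": {"g1": [10 + r, 10 + r, 10 - r, 10 - r],
                   "g2": [4.0, 6.0, 5.0, 5.0]},
            "c2": {"g1": [8 + r, 8 + r, 8 - r, 8 - r],
                   "g2": [5.0, 5.0, 4.0, 6.0]},
        })

    def test_snr_c_hand_example(self):
        # mu1=10, mu2=8, sigma1=sigma2=2 -> 2/4 = 0.5
        ds = self._two_class_ds()
        c1 = ds.samples_of("c1")
        c2 = ds.samples_of("c2")
        ranking = snr_c_scores(ds, c1, c2)
        score = dict(zip(ranking.genes, ranking.scores))["g1"]
        assert score == pytest.approx(0.5, rel=1e-12)

    def test_welch_hand_example(self):
        # mu1=10, mu2=8, sigma=2, n=4 -> 2/sqrt(2) = 1.4142
        ds = self._two_class_ds()
        ranking = welch_t_scores(ds, ds.samples_of("c1"), ds.samples_of("c2"))
        score = dict(zip(ranking.genes, ranking.scores))["g1"]
        assert score == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_identical_classes_score_zero(self):
        ds = _multi_condition_ds({
            "c1": {"g1": [1.0, 2.0, 3.0]},
            "c2": {"g1": [1.0, 2.0, 3.0]},
        })
        for fn in (snr_c_scores, welch_t_scores):
            r = fn(ds, ds.samples_of("c1"), ds.samples_of("c2"))
            assert r.scores[0] == 0.0

    def test_welch_matches_scipy(self, rng):
        ds, _ = generate(default_config(n_genes=40, n_planted_per_condition=2, seed=9))
        c1 = ds.samples_of(sorted(ds.conditions)[0])
        c2 = [s for s in ds.sample_ids if s not in set(c1)]
        ranking = welch_t_scores(ds, c1, c2)
        got = dict(zip(ranking.genes, ranking.scores))
        ref = stats.ttest_ind(ds.matrix(c1), ds.matrix(c2), axis=1, equal_var=False)
        for g, t in zip(ds.genes, np.abs(ref.statistic)):
            assert got[g] == pytest.approx(t, rel=1e-10)

    def test_two_class_scores_match_scalar_oracles(self):
        ds = self._two_class_ds()
        c1, c2 = ds.samples_of("c1"), ds.samples_of("c2")
        snr = dict(zip(*[snr_c_scores(ds, c1, c2).genes,
                         snr_c_scores(ds, c1, c2).scores]))
        wel = dict(zip(*[welch_t_scores(ds, c1, c2).genes,
                         welch_t_scores(ds, c1, c2).scores]))
        for g in ds.genes:
            assert snr[g] == pytest.approx(snr_c_scalar(ds, c1, c2, g), rel=1e-12)
            assert wel[g] == pytest.approx(welch_scalar(ds, c1, c2, g), rel=1e-12)

    def test_welch_and_snr_c_agree_with_equal_n_and_sd(self, rng):
        # class 2 = class 1 shifted per gene: identical per-gene sds by design
        base = rng.normal(size=(10, 6))
        shift = rng.normal(scale=3, size=10)
        vals = {f"g{i:02d}": list(base[i]) + list(base[i] + shift[i]) for i in range(10)}
        meta = ([(f"a{j}", "c1", "fa", float(j), 1) for j in range(6)]
                + [(f"b{j}", "c2", "fb", float(j), 1) for j in range(6)])
        ds = build_dataset(vals, meta)
        c1, c2 = ds.samples_of("c1"), ds.samples_of("c2")
        assert snr_c_scores(ds, c1, c2).genes == welch_t_scores(ds, c1, c2).genes


class TestScaleInvariance:
    @settings(max_examples=10, deadline=None)
    @given(st.floats(0.1, 50.0))
    def test_rankings_invariant_under_positive_scaling(self, c):
        ds, _ = generate(default_config(n_genes=30, n_planted_per_condition=2, seed=17))
        scaled = ds.with_values(ds.array * c)
        cid = sorted(ds.conditions)[0]
        assert rsnr_ranking(ds, cid).genes == rsnr_ranking(scaled, cid).genes
        c1 = ds.samples_of(cid)
        c2 = [s for s in ds.sample_ids if s not in set(c1)]
        assert (snr_c_scores(ds, c1, c2).genes
                == snr_c_scores(scaled, c1, c2).genes)
        assert (welch_t_scores(ds, c1, c2).genes
                == welch_t_scores(scaled, c1, c2).genes)


class TestRandomSelection:
    def test_reproducible_and_complete(self):
        genes = [f"g{i}" for i in range(20)]
        a = random_selection(genes, 5, seed=42)
        b = random_selection(genes, 5, seed=42)
        assert a.genes == b.genes
        assert sorted(random_selection(genes, 20, seed=1).genes) == sorted(genes)
        with pytest.raises(ValueError):
            random_selection(genes, 21, seed=1)

    def test_single_draw_frequencies_are_uniform(self):
        genes = [f"g{i}" for i in range(5)]
        draws = [random_selection(genes, 1, seed=s).genes[0] for s in range(2000)]
        counts = np.array([draws.count(g) for g in genes])
        # binomial(2000, 0.2): 5 sigma band around 400
        sigma = np.sqrt(2000 * 0.2 * 0.8)
        assert np.all(np.abs(counts - 400) < 5 * sigma)


class TestStringSelection:
    LINKS = InteractionSet([("a", "b", 950), ("b", "c", 400)])

    def test_threshold(self):
        genes = ["a", "b", "c", "d"]
        assert string_gene_selection(genes, self.LINKS, 900) == ["a", "b"]
        kept = string_link_selection(genes, self.LINKS, 900)
        assert kept.pairs == [("a", "b")]

    def test_cutoff_zero_keeps_every_linked_gene(self):
        genes = ["a", "b", "c", "d"]
        assert string_gene_selection(genes, self.LINKS, 0) == ["a", "b", "c"]

    def test_gene_and_link_selection_agree_at_every_cutoff(self, rng):
        genes = [f"g{i}" for i in range(12)]
        pairs = {(genes[i], genes[j]): int(rng.integers(1, 1001))
                 for i in range(12) for j in range(i + 1, 12)
                 if rng.random() < 0.3}
        links = InteractionSet([(a, b, s) for (a, b), s in pairs.items()])
        for cutoff in (0, 250, 500, 750, 900):
            try:
                by_gene = set(string_gene_selection(genes, links, cutoff))
                by_link = string_link_selection(genes, links, cutoff).genes()
            except UndefinedScoreError:
                continue
            assert by_gene == by_link

    def test_empty_selection_reports_cutoff(self):
        with pytest.raises(UndefinedScoreError, match="999"):
            string_gene_selection(["a", "b", "c"], self.LINKS, 999)

    def test_links_to_genes_off_the_array_do_not_count(self):
        # (b, c) is dropped because c is off the array; (a, b) survives
        assert string_gene_selection(["a", "b", "d"], self.LINKS, 0) == ["a", "b"]
        with pytest.raises(UndefinedScoreError):
            string_gene_selection(["a", "d"], self.LINKS, 0)


class TestSections:
    def _ranking(self):
        return GeneRanking.from_scores(
            "c", "rsnr", [f"g{i}" for i in range(10)], np.arange(10, 0, -1.0))

    def test_top_whole_list(self):
        r = self._ranking()
        assert select_top(r, 10) == r.genes

    def test_bottom_section(self):
        r = self._ranking()
        assert select_section(r, 9, 2) == r.genes[-2:]

    def test_out_of_range_rejected(self):
        r = self._ranking()
        with pytest.raises(ValueError):
            select_section(r, 10, 2)

    def test_equal_scores_tie_break_by_gene_id(self):
        r = GeneRanking.from_scores("c", "m", ["gB", "gA", "gC"], [1.0, 1.0, 2.0])
        assert r.genes == ["gC", "gA", "gB"]
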