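"""Bisulfite alignment, CpG extraction, estimation, QC, stability."""

import numpy as np
import pandas as pd
import pytest

from sctem import _seq, demux, methylation, reference, simulate
from sctem.errors import (ConfigurationError, InsufficientDataError,
                          InvalidParameterError)
from sctem.methylation import CTX_CHG, CTX_CHH, CTX_CPG
from sctem.simulate import ReadPair


def _perfect_params(**kw):
    base = dict(cell_id="c", well_id="A1", true_methylation=0.8,
                conversion_failure=0.0, inappropriate_conversion=0.0,
                amp_bias=0.0, n_read_pairs=200, seq_error=0.0, seed=1)
    base.update(kw)
    return simulate.CellSimParams(**base)


class TestAlignment:
    def test_planted_reads_align_to_truth_locus(self, consensus):
        """Error-free reads from a single-copy genome align uniquely at
        their true position with zero mismatches."""
        genome, annots = reference.synth_genome(consensus, 1, 0.0, seed=2)
        plate = reference.design_plate(consensus, 4, seed=3)
        pairs, truth = simulate.simulate_cell(
            genome, annots, plate, _perfect_params(n_read_pairs=30))
        ref = methylation.BisulfiteReference(genome)
        trimmed, _ = demux.trim_all(
            demux.demultiplex(pairs, plate)[0]["A1"], 10, 10)
        aligned = methylation.align_pairs(trimmed, ref)
        assert len(aligned) == len(trimmed)
        assert (aligned["mm1"] == 0).all() and (aligned["mm2"] == 0).all()
        prov = truth.provenance.set_index("read_id")
        ins = prov.loc[aligned["read_id"], "insert_start"].to_numpy()
        # forward mate starts 10 bases into the insert (end trimming)
        left = np.minimum(aligned["start1"], aligned["start2"])
        assert np.array_equal(left, ins + 10)

    def test_identical_copies_force_ambiguity(self, consensus):
        """A read matching two identical TE copies cannot be placed."""
        genome, annots = reference.synth_genome(consensus, 2, 0.0, seed=2)
        chrom = annots[0].chrom
        seg = genome[chrom][annots[0].start + 40:annots[0].start + 100]
        read = _seq.ct_convert(seg)
        hits = methylation.align_bisulfite(
            [("r0", read)], methylation.BisulfiteReference(genome))
        assert len(hits) == 1
        assert hits[0].unique is False

    def test_converted_reference_segment_aligns_exactly(self, small_world):
        """Full conversion is idempotent in reduced space: a converted
        reference substring aligns at its origin with 0 mismatches."""
        chrom = small_world["annots"][0].chrom
        a = small_world["annots"][5]
        seg = small_world["genome"][chrom][a.start + 20:a.start + 110]
        read = _seq.ct_convert(seg)
        hits = methylation.align_bisulfite([("r0", read)],
                                           small_world["ref"])
        assert len(hits) == 1
        h = hits[0]
        assert h.unique and h.n_mismatches == 0
        assert h.start == a.start + 20 and h.strand_config == "OT"

    def test_truth_table_agreement_with_divergent_genome(self, cell_library):
        """Simulated library on a 60-copy diverged genome: nearly all
        aligned pairs land on their true template locus."""
        aligned = cell_library["aligned"]
        assert len(aligned) / len(cell_library["trimmed"]) >= 0.8
        prov = cell_library["truth"].provenance.set_index("read_id")
        ins = prov.loc[aligned["read_id"], "insert_start"].to_numpy()
        left = np.minimum(aligned["start1"], aligned["start2"]).to_numpy()
        assert (np.abs(left - ins - 10) <= 1).mean() >= 0.95

    def test_empty_reference_rejected(self):
        with pytest.raises(ConfigurationError):
            methylation.BisulfiteReference({})


class TestExtraction:
    def _one_pair_frame(self, start2=0, config2="OT"):
        return pd.DataFrame({
            "pair_idx": [0], "read_id": ["r0"],
            "start1": [0], "len1": [4], "config1": ["OT"], "mm1": [0],
            "start2": [start2], "len2": [4], "config2": [config2],
            "mm2": [0],
        })

    def test_smallest_cpg_call(self):
        """Reference ACGT, read ACGT on OT: one methylated CpG at
        1-based position 2."""
        ref = methylation.BisulfiteReference({"c": "ACGT"})
        pairs = [ReadPair("r0", "ACGT", "IIII", "ACGT", "IIII")]
        calls = methylation.extract_methylation(
            self._one_pair_frame(), pairs, ref)
        cpg = calls[calls["context"] == CTX_CPG]
        assert len(cpg) == 1
        cov = methylation.cov_from_calls(calls, ref)
        assert list(cov.itertuples(index=False))[0][:2] == ("c", 2)
        assert cov["meth_percent"].iloc[0] == 100.0

    def test_mate_overlap_counted_once_first_mate_wins(self):
        ref = methylation.BisulfiteReference({"c": "ACGT"})
        # mate 1 reads C (methylated), mate 2 reads T at the same site
        pairs = [ReadPair("r0", "ACGT", "IIII", "ATGT", "IIII")]
        calls = methylation.extract_methylation(
            self._one_pair_frame(), pairs, ref)
        cpg = calls[calls["context"] == CTX_CPG]
        assert len(cpg) == 1
        assert bool(cpg["methylated"].iloc[0]) is True

    def test_saturated_cell_has_no_unmethylated_cpg(self, small_world):
        """Fully methylated cell with perfect chemistry: every CpG
        record is 100%, every non-CpG call unmethylated."""
        pairs, _ = simulate.simulate_cell(
            small_world["genome"], small_world["annots"],
            small_world["plate"],
            _perfect_params(true_methylation=1.0, n_read_pairs=300))
        trimmed, _ = demux.trim_all(
            demux.demultiplex(pairs, small_world["plate"])[0]["A1"])
        aligned = methylation.align_pairs(trimmed, small_world["ref"])
        calls = methylation.extract_methylation(aligned, trimmed,
                                                small_world["ref"])
        cov = methylation.cov_from_calls(calls, small_world["ref"])
        assert (cov["count_unmethylated"] == 0).all()
        assert (cov["meth_percent"] == 100.0).all()
        noncpg = calls[calls["context"] != CTX_CPG]
        assert len(noncpg) > 0
        assert not noncpg["methylated"].any()

    def test_estimate_matches_truth_states(self, cell_library):
        """Site-mean estimate agrees with the simulator's realized
        (post-chemistry) states at the covered sites."""
        truth = cell_library["truth"]
        cov = cell_library["cov"]
        obs = pd.Series(truth.site_observed.astype(float),
                        index=truth.site_pos)
        covered = obs.reindex(cov["pos"].to_numpy() - 1).dropna()
        expected = 100.0 * covered.mean()
        est = cov["meth_percent"].mean()
        se = 100.0 * np.sqrt(covered.mean() * (1 - covered.mean())
                             / len(covered))
        assert abs(est - expected) <= max(3 * se, 1.0)


class TestCellEstimate:
    def test_site_mean_is_unweighted(self):
        cov = pd.DataFrame({
            "chrom": ["c"] * 3, "pos": [2, 10, 20],
            "meth_percent": [100.0, 50.0, 0.0],
            "count_methylated": [2, 1, 0],
            "count_unmethylated": [0, 1, 2],
        })
        cm = methylation.cell_methylation(cov, [], te_site_threshold=0)
        assert cm.mean_site_methylation == 50.0

    def test_site_mean_differs_from_read_weighted(self):
        cov = pd.DataFrame({
            "chrom": ["c", "c"], "pos": [2, 10],
            "meth_percent": [100.0, 0.0],
            "count_methylated": [10, 0],
            "count_unmethylated": [0, 1],
        })
        cm = methylation.cell_methylation(cov, [], te_site_threshold=0)
        assert cm.mean_site_methylation == 50.0
        assert cm.read_weighted_methylation == pytest.approx(100 * 10 / 11)

    @pytest.mark.parametrize("n_annots,threshold,expected", [
        (999, 1000, False),   # one short of the default threshold
        (1000, 1000, True),
        (500, 500, True),     # low-coverage preset boundary
        (499, 500, False),
    ])
    def test_qc_element_threshold(self, n_annots, threshold, expected):
        annots = [
            reference.TEAnnotation("c", i * 10, i * 10 + 5, "+", "AluY",
                                   f"te{i}")
            for i in range(n_annots)
        ]
        cov = pd.DataFrame({
            "chrom": ["c"] * n_annots,
            "pos": [i * 10 + 1 for i in range(n_annots)],
            "meth_percent": [100.0] * n_annots,
            "count_methylated": [1] * n_annots,
            "count_unmethylated": [0] * n_annots,
        })
        cm = methylation.cell_methylation(cov, annots, threshold)
        assert cm.qc_pass is expected
        assert cm.n_unique_te_annotations == n_annots

    def test_empty_cov_fails_qc(self):
        cov = pd.DataFrame(columns=["chrom", "pos", "meth_percent",
                                    "count_methylated",
                                    "count_unmethylated"])
        cm = methylation.cell_methylation(cov, [], 1000)
        assert cm.qc_pass is False
        assert np.isnan(cm.mean_site_methylation)


class TestConversionQC:
    def test_perfect_chemistry_zero_noncpg_rate(self, small_world):
        pairs, _ = simulate.simulate_cell(
            small_world["genome"], small_world["annots"],
            small_world["plate"], _perfect_params(n_read_pairs=100))
        trimmed, _ = demux.trim_all(
            demux.demultiplex(pairs, small_world["plate"])[0]["A1"])
        aligned = methylation.align_pairs(trimmed, small_world["ref"])
        calls = methylation.extract_methylation(aligned, trimmed,
                                                small_world["ref"])
        chg, chh, flag = methylation.conversion_qc(calls)
        assert chg == 0.0 and chh == 0.0 and flag is False

    def test_failure_rate_recovered(self, small_world):
        """A 0.67% conversion-failure cell shows a matching CHG rate
        (the published conversion-QC regime)."""
        pairs, _ = simulate.simulate_cell(
            small_world["genome"], small_world["annots"],
            small_world["plate"],
            _perfect_params(conversion_failure=0.0067,
                            n_read_pairs=4000, seed=17))
        trimmed, _ = demux.trim_all(
            demux.demultiplex(pairs, small_world["plate"])[0]["A1"])
        aligned = methylation.align_pairs(trimmed, small_world["ref"])
        calls = methylation.extract_methylation(aligned, trimmed,
                                                small_world["ref"])
        chg, chh, flag = methylation.conversion_qc(calls)
        # chemistry outcomes are fixed per site; the sampling unit for
        # the binomial error is the distinct CHG site count
        n_sites = calls.loc[calls["context"] == CTX_CHG, "gpos"].nunique()
        tol = 100 * 3 * np.sqrt(0.0067 * (1 - 0.0067) / n_sites)
        assert abs(chg - 0.67) <= tol
        assert flag is False

    def test_threshold_flag(self):
        calls = pd.DataFrame({
            "pair_idx": range(200), "mate": 1,
            "gpos": range(200), "strand": "+",
            "context": [CTX_CHG] * 200,
            "methylated": [True] * 5 + [False] * 195,  # 2.5%
        })
        chg, _, flag = methylation.conversion_qc(calls, ceiling=2.0)
        assert chg == pytest.approx(2.5)
        assert flag is True

    def test_no_noncpg_calls_raises_flag(self):
        calls = pd.DataFrame({
            "pair_idx": [0], "mate": [1], "gpos": [3], "strand": ["+"],
            "context": [CTX_CPG], "methylated": [True],
        })
        chg, chh, flag = methylation.conversion_qc(calls)
        assert np.isnan(chg) and flag is True


class TestBootstrap:
    def test_full_depth_and_single_rep_have_zero_range(self, cell_library):
        calls = cell_library["calls"]
        n_pairs = calls["pair_idx"].nunique()
        table, ranges = methylation.bootstrap_stability(
            calls, [n_pairs], n_reps=5, seed=1)
        assert ranges["range"].iloc[0] == 0.0
        table, ranges = methylation.bootstrap_stability(
            calls, [200], n_reps=1, seed=1)
        assert ranges["range"].iloc[0] == 0.0

    def test_range_shrinks_with_depth(self, cell_library):
        calls = cell_library["calls"]
        _, ranges = methylation.bootstrap_stability(
            calls, [100, 1500], n_reps=20, seed=7)
        r = ranges.set_index("depth")["range"]
        assert r[1500] <= r[100]

    def test_excessive_depth_skipped_with_warning(self, cell_library):
        with pytest.warns(UserWarning, match="skipped"):
            table, _ = methylation.bootstrap_stability(
                cell_library["calls"], [10 ** 9], n_reps=2, seed=1)
        assert len(table) == 0

    def test_invalid_reps_rejected(self, cell_library):
        with pytest.raises(InvalidParameterError):
            methylation.bootstrap_stability(cell_library["calls"], [10],
                                            n_reps=0)


class TestTiles:
    def test_single_site_single_tile(self):
        cov = pd.DataFrame({"chrom": ["c"], "pos": [11],
                            "meth_percent": [75.0],
                            "count_methylated": [3],
                            "count_unmethylated": [1]})
        tiles, glob = methylation.bulk_tile_methylation(cov, 3000)
        assert len(tiles) == 1 and glob == 75.0

    def test_uniform_sites_give_uniform_global(self):
        cov = pd.DataFrame({"chrom": ["c"] * 10,
                            "pos": np.arange(1, 30001, 3000),
                            "meth_percent": [100.0] * 10,
                            "count_methylated": [1] * 10,
                            "count_unmethylated": [0] * 10})
        _, glob = methylation.bulk_tile_methylation(cov, 3000)
        assert glob == 100.0

    def test_matches_brute_force_tiling(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(np.arange(1, 20001), 300, replace=False))
        pct = rng.uniform(0, 100, 300)
        cov = pd.DataFrame({"chrom": "c", "pos": pos, "meth_percent": pct,
                            "count_methylated": 1,
                            "count_unmethylated": 0})
        tiles, glob = methylation.bulk_tile_methylation(cov, 3000)
        # brute-force oracle
        expected = {}
        for p, v in zip(pos, pct):
            expected.setdefault((p - 1) // 3000, []).append(v)
        want = {t: np.mean(v) for t, v in expected.items()}
        got = dict(zip(tiles["tile"], tiles["meth_percent"]))
        assert got.keys() == want.keys()
        for t in want:
            assert got[t] == pytest.approx(want[t])
        assert glob == pytest.approx(np.mean(list(want.values())))


def _uniform_cov(level, n_in=30, n_out=30, offset=0.0):
    """Synthetic per-cell cov: sites 0..n_in-1 inside the family
    annotation block, the rest outside."""
    pos = np.concatenate([np.arange(1, n_in + 1),
                          np.arange(100001, 100001 + n_out)])
    pct = np.concatenate([np.full(n_in, level + offset),
                          np.full(n_out, level)])
    return pd.DataFrame({"chrom": "c", "pos": pos, "meth_percent": pct,
                         "count_methylated": 1, "count_unmethylated": 0})


class TestSurrogate:
    ANNOTS = [reference.TEAnnotation("c", 0, 50, "+", "AluY", "te0")]

    def test_uniform_cells_give_identity_fit(self):
        covs = {f"c{i}": _uniform_cov(lvl)
                for i, lvl in enumerate([30.0, 50.0, 70.0, 90.0])}
        fit = methylation.surrogate_validation(covs, self.ANNOTS, "AluY")
        assert fit["r2"] == pytest.approx(1.0, abs=1e-12)
        assert fit["slope"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_recovered(self):
        """TE methylation sitting a fixed margin above the global level
        yields slope ~1 and intercept ~ the margin."""
        rng = np.random.default_rng(3)
        covs = {}
        for i in range(12):
            lvl = rng.uniform(30, 90)
            covs[f"c{i}"] = _uniform_cov(lvl, offset=6.8)
        fit = methylation.surrogate_validation(covs, self.ANNOTS, "AluY")
        # global mean includes the offset sites, so the fitted
        # intercept is the within-cell TE-minus-global gap
        gap = 6.8 * (1 - 30 / 60)
        assert fit["slope"] == pytest.approx(1.0, abs=0.01)
        assert fit["intercept"] == pytest.approx(gap, abs=0.5)
        assert fit["r2"] > 0.99

    def test_independent_te_methylation_gives_low_r2(self):
        rng = np.random.default_rng(4)
        covs = {}
        for i in range(30):
            cov = _uniform_cov(rng.uniform(30, 90))
            te_level = rng.uniform(30, 90)  # unrelated to global
            cov.loc[:29, "meth_percent"] = te_level
            covs[f"c{i}"] = cov
        fit = methylation.surrogate_validation(covs, self.ANNOTS, "AluY")
        assert fit["r2"] < 0.5

    def test_too_few_cells_rejected(self):
        covs = {"a": _uniform_cov(50.0), "b": _uniform_cov(60.0)}
        with pytest.raises(InsufficientDataError):
            methylation.surrogate_validation(covs, self.ANNOTS, "AluY")
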