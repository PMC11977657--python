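"""Detection filtering, gene collapse/ranking, BH adjustment, delta-delta-Ct."""

import numpy as np
import pandas as pd
import pytest

from mirscape import (
    CtTable,
    ExpressionMatrix,
    ProbeAnnotation,
    RankedList,
    bh_adjust,
    collapse_and_rank,
    ddct_relative_expression,
    detection_filter,
)


def make_matrix(values: dict, conditions=None, nc=()):
    df = pd.DataFrame(values).T
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    conditions = conditions or {
        c: ("treated" if j < df.shape[1] // 2 else "control") for j, c in enumerate(df.columns)
    }
    return ExpressionMatrix(values=df, conditions=conditions, negative_controls=set(nc))


class TestDetectionFilter:
    def test_probe_above_all_controls_retained(self):
        m = make_matrix({"sig": [100, 100], "nc1": [1, 2], "nc2": [2, 1]}, nc=["nc1", "nc2"])
        filtered, log = detection_filter(m)
        assert list(filtered.values.index) == ["sig"]
        assert log.set_index("probe_id").at["sig", "detection_p"] == 0.0

    def test_probe_at_control_median_removed(self):
        nc = {f"nc{i}": [float(i), float(i)] for i in range(10)}
        m = make_matrix({"mid": [4.5, 4.5], **nc}, nc=list(nc))
        filtered, log = detection_filter(m)
        assert "mid" not in filtered.values.index
        assert log.set_index("probe_id").at["mid", "detection_p"] > 0.01

    def test_against_per_probe_empirical_oracle(self, rng):
        # 100 strong probes 10 SD above 100 background-like probes drawn
        # from the negative-control distribution
        nc_vals = rng.normal(10, 1, size=(100, 4))
        signal = rng.normal(20, 1, size=(100, 4))
        lookalike = rng.normal(10, 1, size=(50, 4))
        values = np.clip(np.vstack([signal, lookalike, nc_vals]), 0, None)
        ids = (
            [f"sig{i}" for i in range(100)]
            + [f"like{i}" for i in range(50)]
            + [f"nc{i}" for i in range(100)]
        )
        df = pd.DataFrame(values, index=ids, columns=["a", "b", "c", "d"])
        m = ExpressionMatrix(
            values=df,
            conditions={"a": "treated", "b": "treated", "c": "control", "d": "control"},
            negative_controls={f"nc{i}" for i in range(100)},
        )
        filtered, log = detection_filter(m, alpha=0.01)
        pooled = np.sort(df.loc[[f"nc{i}" for i in range(100)]].to_numpy().ravel())
        expected_kept = {
            pid
            for pid in ids
            if not pid.startswith("nc")
            and np.mean(pooled >= df.loc[pid].mean()) <= 0.01
        }
        assert set(filtered.values.index) == expected_kept
        assert set(f"sig{i}" for i in range(100)) <= expected_kept

    def test_idempotent(self, rng):
        nc = {f"nc{i}": list(rng.normal(5, 1, 3)) for i in range(10)}
        sig = {f"p{i}": list(rng.normal(50, 1, 3)) for i in range(5)}
        m = make_matrix({**sig, **nc}, nc=list(nc))
        once, _ = detection_filter(m)
        # a filtered matrix has no controls left; refiltering is a no-op by contract
        assert set(once.values.index) == set(sig)
        assert once.negative_controls == set()

    def test_requires_negative_controls(self):
        m = make_matrix({"p": [1, 2]})
        with pytest.raises(ValueError, match="negative-control"):
            detection_filter(m)


def annotation_for(genes: dict[str, str], full_utr=True) -> ProbeAnnotation:
    return ProbeAnnotation(
        table=pd.DataFrame(
            {
                "probe_id": list(genes),
                "gene_id": list(genes.values()),
                "has_full_utr": full_utr,
            }
        )
    )


class TestCollapseAndRank:
    def test_orders_by_fold_change_ascending(self):
        # log2FCs of -2, 0, +1 realised through intensities
        vals = {
            "pA": [2**6 - 1, 2**8 - 1],  # treated, control -> -2
            "pB": [2**8 - 1, 2**8 - 1],  # 0
            "pC": [2**9 - 1, 2**8 - 1],  # +1
        }
        m = make_matrix(vals, conditions={"s0": "treated", "s1": "control"})
        ranked = collapse_and_rank(m, annotation_for({"pA": "A", "pB": "B", "pC": "C"}))
        assert ranked.genes == ["A", "B", "C"]
        assert np.allclose(ranked.table["log2fc"], [-2, 0, 1])

    def test_gene_represented_by_largest_absolute_fold_change(self):
        vals = {
            "p1": [2 ** (8 - 1.5) - 1, 2**8 - 1],  # gene G at -1.5
            "p2": [2 ** (8 + 0.2) - 1, 2**8 - 1],  # gene G at +0.2
            "p3": [2**8 - 1, 2**8 - 1],  # gene H at 0
        }
        m = make_matrix(vals, conditions={"s0": "treated", "s1": "control"})
        ranked = collapse_and_rank(m, annotation_for({"p1": "G", "p2": "G", "p3": "H"}))
        fc = ranked.table.set_index("gene_id")["log2fc"]
        assert np.isclose(fc["G"], -1.5)

    def test_genes_without_full_utr_excluded(self):
        vals = {"p1": [3.0, 3.0], "p2": [3.0, 3.0]}
        m = make_matrix(vals, conditions={"s0": "treated", "s1": "control"})
        ann = ProbeAnnotation(
            table=pd.DataFrame(
                {"probe_id": ["p1", "p2"], "gene_id": ["A", "B"], "has_full_utr": [True, False]}
            )
        )
        assert collapse_and_rank(m, ann).genes == ["A"]

    def test_row_permutation_leaves_output_identical(self, rng):
        vals = {f"p{i}": list(rng.uniform(1, 100, 4)) for i in range(20)}
        conditions = {"s0": "treated", "s1": "treated", "s2": "control", "s3": "control"}
        ann = annotation_for({f"p{i}": f"G{i}" for i in range(20)})
        m1 = make_matrix(vals, conditions=conditions)
        shuffled = dict(reversed(vals.items()))
        m2 = make_matrix(shuffled, conditions=conditions)
        pd.testing.assert_frame_equal(
            collapse_and_rank(m1, ann).table, collapse_and_rank(m2, ann).table
        )

    def test_recovers_generator_truth_order(self, small_synthetic):
        cfg, universe, matrix, annotation, truth = small_synthetic
        filtered, _ = detection_filter(matrix)
        ranked = collapse_and_rank(filtered, annotation)
        expected = truth.sort_values(["observed_log2fc", "gene_id"])["gene_id"].tolist()
        assert ranked.genes == expected
        obs = truth.set_index("gene_id")["observed_log2fc"]
        assert np.allclose(
            ranked.table["log2fc"], [obs[g] for g in ranked.genes], atol=1e-9
        )


def bh_oracle(p):
    """Step-up BH, re-implemented from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


class TestBhAdjust:
    def test_single_p_unchanged(self):
        adj, flags = bh_adjust([0.04])
        assert np.isclose(adj[0], 0.04) and flags[0]

    def test_step_up_arithmetic(self):
        adj, _ = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_against_brute_force_oracle(self, rng):
        p = rng.uniform(size=1000)
        adj, flags = bh_adjust(p, q=0.1)
        expected = bh_oracle(p)
        assert np.allclose(adj, expected)
        assert np.array_equal(flags, expected <= 0.1)

    def test_empty_input(self):
        adj, flags = bh_adjust([])
        assert adj.size == 0 and flags.size == 0


def ct_table(rows, refs, ref_sample="ref"):
    return CtTable(
        data=pd.DataFrame(rows, columns=["sample", "assay", "replicate", "ct"]),
        reference_assays=refs,
        reference_sample=ref_sample,
    )


class TestDdct:
    def test_reference_sample_maps_to_one(self):
        rows = [(s, a, 1, ct) for s in ("ref", "x") for a, ct in [("T", 22.0), ("R", 20.0)]]
        rel = ddct_relative_expression(ct_table(rows, ["R"]))
        assert np.isclose(rel.at["ref", "T"], 1.0)
        assert np.isclose(rel.at["x", "T"], 1.0)

    @pytest.mark.parametrize("ddct, expected", [(-1.0, 2.0), (2.0, 0.25)])
    def test_closed_form(self, ddct, expected):
        rows = [
            ("ref", "T", 1, 22.0), ("ref", "R", 1, 20.0),
            ("x", "T", 1, 22.0 + ddct), ("x", "R", 1, 20.0),
        ]
        rel = ddct_relative_expression(ct_table(rows, ["R"]))
        assert np.isclose(rel.at["x", "T"], expected)

    def test_three_reference_panel_hand_computed(self):
        # reference panel Cts averaged arithmetically before the delta
        rows = []
        for s, t_ct, refs in [("ref", 24.0, (20.0, 21.0, 22.0)), ("x", 23.0, (20.5, 21.5, 19.0))]:
            rows.append((s, "T", 1, t_ct))
            for i, rc in enumerate(refs):
                rows.append((s, f"R{i}", 1, rc))
        rel = ddct_relative_expression(ct_table(rows, ["R0", "R1", "R2"]))
        dct_ref = 24.0 - np.mean([20.0, 21.0, 22.0])
        dct_x = 23.0 - np.mean([20.5, 21.5, 19.0])
        assert np.isclose(rel.at["x", "T"], 2 ** -(dct_x - dct_ref))

    def test_shift_invariance(self):
        # adding a constant to one sample's target and reference Cts together
        base = [
            ("ref", "T", 1, 25.0), ("ref", "R", 1, 21.0),
            ("x", "T", 1, 24.0), ("x", "R", 1, 21.5),
        ]
        shifted = [
            (s, a, r, ct + (3.7 if s == "x" else 0.0)) for s, a, r, ct in base
        ]
        a = ddct_relative_expression(ct_table(base, ["R"]))
        b = ddct_relative_expression(ct_table(shifted, ["R"]))
        pd.testing.assert_frame_equal(a, b)

    def test_missing_reference_raises(self):
        rows = [("ref", "T", 1, 22.0)]
        with pytest.raises(ValueError, match="reference assays"):
            ct_table(rows, ["R"])


class TestRankedList:
    def test_rejects_duplicates_and_disorder(self):
        with pytest.raises(ValueError, match="one entry per gene"):
            RankedList(table=pd.DataFrame({"gene_id": ["a", "a"], "log2fc": [0.0, 1.0]}))
        with pytest.raises(ValueError, match="non-decreasing"):
            RankedList(table=pd.DataFrame({"gene_id": ["a", "b"], "log2fc": [1.0, 0.0]}))

    def test_from_stats_orders_with_gene_id_ties(self):
        ranked = RankedList.from_stats({"b": 0.0, "a": 0.0, "c": -1.0})
        assert ranked.genes == ["c", "a", "b"]
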