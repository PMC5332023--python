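"""Threshold clustering, overrides, and CCS/UCS/DCL evidence integration."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from hyladelim import datasets
from hyladelim.delimit import (
    apply_overrides,
    cluster_lineages,
    integrate_evidence,
)


def scipy_single_linkage(summary: pd.DataFrame, threshold: float):
    """Independent oracle: scipy single-linkage cut at the threshold."""
    clades = sorted(set(summary["clade_a"]) | set(summary["clade_b"]))
    idx = {c: i for i, c in enumerate(clades)}
    mat = np.zeros((len(clades), len(clades)))
    for _, r in summary.iterrows():
        i, j = idx[r["clade_a"]], idx[r["clade_b"]]
        mat[i, j] = mat[j, i] = r["mean"]
    labels = fcluster(
        linkage(squareform(mat), method="single"),
        t=threshold,
        criterion="distance",
    )
    groups: dict[int, set] = {}
    for c, lab in zip(clades, labels):
        groups.setdefault(lab, set()).add(c)
    return tuple(sorted(tuple(sorted(g)) for g in groups.values()))


def random_summary(rng, n_clades=6):
    clades = [chr(65 + i) for i in range(n_clades)]
    rows = [
        {"clade_a": a, "clade_b": b, "mean": float(rng.uniform(0.005, 0.12))}
        for i, a in enumerate(clades)
        for b in clades[i + 1 :]
    ]
    return pd.DataFrame(rows)


class TestClusterLineages:
    def test_published_matrix_merges_only_the_two_least_divergent(self):
        # at 3% the only inter-clade mean below threshold is F-H (2.5%)
        part = cluster_lineages(datasets.clade_distance_means(), 0.03)
        assert len(part) == 8
        assert ("F", "H") in part

    def test_matches_scipy_single_linkage_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            summ = random_summary(rng)
            thr = float(rng.uniform(0.01, 0.1))
            assert cluster_lineages(summ, thr) == scipy_single_linkage(
                summ, thr
            )

    def test_threshold_zero_gives_singletons(self):
        part = cluster_lineages(datasets.clade_distance_means(), 0.0)
        assert all(len(g) == 1 for g in part)
        assert len(part) == 9

    def test_threshold_one_gives_single_group(self):
        part = cluster_lineages(datasets.clade_distance_means(), 1.0)
        assert len(part) == 1

    def test_permutation_invariance(self):
        summ = datasets.clade_distance_means()
        rng = np.random.default_rng(5)
        base = cluster_lineages(summ, 0.05)
        for _ in range(10):
            shuffled = summ.sample(frac=1, random_state=rng.integers(1 << 31))
            # also swap the a/b orientation of half the rows
            flip = shuffled.sample(frac=0.5, random_state=1).index
            shuffled.loc[flip, ["clade_a", "clade_b"]] = shuffled.loc[
                flip, ["clade_b", "clade_a"]
            ].values
            assert cluster_lineages(shuffled, 0.05) == base

    def test_raising_threshold_never_increases_group_count(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            summ = random_summary(rng)
            counts = [
                len(cluster_lineages(summ, t))
                for t in np.linspace(0, 0.13, 25)
            ]
            assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_missing_pair_rejected_by_name(self):
        summ = datasets.clade_distance_means()
        summ = summ[
            ~((summ.clade_a == "A") & (summ.clade_b == "B"))
        ]
        with pytest.raises(ValueError, match="A, B"):
            cluster_lineages(summ, 0.03)


class TestApplyOverrides:
    def base_partition(self):
        return cluster_lineages(datasets.clade_distance_means(), 0.03)

    def test_split_out_restores_nine_candidates(self):
        part, applied = apply_overrides(
            self.base_partition(), [datasets.clade_f_override()]
        )
        assert len(part) == 9
        assert ("F",) in part and ("H",) in part
        assert applied[0]["lineage"] == "F"
        assert "506 bp" in applied[0]["rationale"]

    def test_empty_override_list_is_identity(self):
        part, applied = apply_overrides(self.base_partition(), [])
        assert part == self.base_partition()
        assert applied == []

    def test_split_out_singleton_is_noop_with_warning(self):
        with pytest.warns(UserWarning, match="no-op"):
            part, _ = apply_overrides(
                self.base_partition(), [("A", "split_out", "already alone")]
            )
        assert part == self.base_partition()

    def test_merge_into(self):
        part, _ = apply_overrides(
            self.base_partition(), [("A", "merge_into:B", "test")]
        )
        assert ("A", "B") in part

    def test_unknown_lineage_rejected(self):
        with pytest.raises(KeyError):
            apply_overrides(self.base_partition(), [("Z", "split_out", "x")])

    def test_unknown_action_rejected(self):
        with pytest.raises(ValueError):
            apply_overrides(self.base_partition(), [("A", "explode", "x")])


class TestIntegrateEvidence:
    def nine_singletons(self):
        return tuple((c,) for c in "ABCDEFGHI")

    def test_published_encoding_yields_five_ccs_four_ucs(self):
        result = integrate_evidence(
            self.nine_singletons(), datasets.evidence_table()
        )
        assert result.counts() == {"CCS": 5, "UCS": 4}
        assert result.status["I"] == "CCS"  # morphology alone confirms
        assert {result.status[c] for c in "DEFG"} == {"UCS"}

    def test_available_but_not_distinct_is_dcl(self):
        ev = pd.DataFrame(
            [("A", "unavailable", "not_distinct")],
            columns=["lineage", "acoustic_status", "morpho_status"],
        )
        result = integrate_evidence((("A",),), ev)
        assert result.status["A"] == "DCL"

    def test_all_unavailable_is_all_ucs(self):
        ev = pd.DataFrame(
            [(c, "unavailable", "unavailable") for c in "ABC"],
            columns=["lineage", "acoustic_status", "morpho_status"],
        )
        result = integrate_evidence((("A",), ("B",), ("C",)), ev)
        assert set(result.status.values()) == {"UCS"}

    def test_ccs_requires_distinct_evidence(self):
        # property: no group without a "distinct" entry is ever CCS
        rng = np.random.default_rng(13)
        statuses = ["distinct", "not_distinct", "unavailable"]
        for _ in range(50):
            ev = pd.DataFrame(
                [
                    (c, rng.choice(statuses), rng.choice(statuses))
                    for c in "ABCDE"
                ],
                columns=["lineage", "acoustic_status", "morpho_status"],
            )
            result = integrate_evidence(tuple((c,) for c in "ABCDE"), ev)
            for _, row in ev.iterrows():
                has_distinct = "distinct" in (
                    row["acoustic_status"],
                    row["morpho_status"],
                )
                if result.status[row["lineage"]] == "CCS":
                    assert has_distinct

    def test_merged_group_reported_as_one_unit(self):
        ev = datasets.evidence_table()
        part = cluster_lineages(datasets.clade_distance_means(), 0.03)
        result = integrate_evidence(part, ev)
        # F and H merged: H's distinct call/morphology carries the group
        assert result.status["F"] == result.status["H"] == "CCS"
        assert result.counts()["CCS"] == 5

    def test_missing_lineage_rejected(self):
        ev = datasets.evidence_table()
        ev = ev[ev.lineage != "I"]
        with pytest.raises(KeyError, match="I"):
            integrate_evidence(self.nine_singletons(), ev)

    def test_invalid_status_rejected(self):
        ev = pd.DataFrame(
            [("A", "loud", "distinct")],
            columns=["lineage", "acoustic_status", "morpho_status"],
        )
        with pytest.raises(ValueError, match="acoustic_status"):
            integrate_evidence((("A",),), ev)

    def test_result_frame_covers_all_lineages(self):
        result = integrate_evidence(
            self.nine_singletons(), datasets.evidence_table()
        )
        frame = result.to_frame()
        assert sorted(frame["lineage"]) == list("ABCDEFGHI")
        assert set(frame["status"]) <= {"CCS", "UCS", "DCL", "not_candidate"}
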