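"""Candidate-species grouping and CCS / UCS / DCL verdicts.

Genetically distinct groups are found by single-linkage agglomeration on
inter-clade mean p-distances: two clades share a group iff they are
connected by a chain of pairwise means at or below the threshold (the
candidate-species rule is strict — groups separated by > 3.0% are candidate
species). Analyst overrides (e.g. splitting out a clade on branch-length
grounds when its distance is an artifact of a short sequence) are explicit,
logged inputs. Each genetically distinct group is then classified:

* CCS — Confirmed Candidate Species: at least one non-genetic character set
  (acoustic or morphological) is independently diagnostic;
* UCS — Unconfirmed Candidate Species: acoustic and morphological data both
  unavailable;
* DCL — Deep Conspecific Lineage: non-genetic data available but not
  diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "EvidenceStatus",
    "Partition",
    "DelimitationResult",
    "cluster_lineages",
    "apply_overrides",
    "integrate_evidence",
]

VALID_STATUS = {"distinct", "not_distinct", "unavailable"}

#: a partition is a sorted tuple of sorted tuples of lineage labels
Partition = tuple[tuple[str, ...], ...]


def _canonical(groups: list[set[str]]) -> Partition:
    return tuple(sorted(tuple(sorted(g)) for g in groups))


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def cluster_lineages(summary: pd.DataFrame, threshold: float) -> Partition:
    """Single-linkage grouping of clades on inter-clade mean distances.

    ``summary`` is the long-format table from
    :func:`hyladelim.gendist.clade_pair_summary` (or any table with columns
    ``clade_a``, ``clade_b``, ``mean``). Clades joined by a chain of means
    <= ``threshold`` share a group. Deterministic and order-independent.
    """
    inter = summary[summary["clade_a"] != summary["clade_b"]]
    clades = sorted(
        set(summary["clade_a"]) | set(summary["clade_b"])
    )
    have = {
        frozenset((a, b))
        for a, b in zip(inter["clade_a"], inter["clade_b"])
    }
    for i, a in enumerate(clades):
        for b in clades[i + 1 :]:
            if frozenset((a, b)) not in have:
                raise ValueError(
                    f"missing inter-clade mean for pair ({a}, {b})"
                )
    uf = _UnionFind(clades)
    for _, row in inter.iterrows():
        if row["mean"] <= threshold:
            uf.union(row["clade_a"], row["clade_b"])
    groups: dict[str, set[str]] = {}
    for c in clades:
        groups.setdefault(uf.find(c), set()).add(c)
    return _canonical(list(groups.values()))


def apply_overrides(
    partition: Partition,
    overrides: list[tuple[str, str, str]],
) -> tuple[Partition, list[dict]]:
    """Apply explicit analyst overrides to a genetic partition.

    Each override is ``(lineage, action, rationale)`` with action either
    ``"split_out"`` (move the lineage into its own singleton group) or
    ``"merge_into:<lineage>"`` (union its group with the group containing
    the named lineage). Returns the new partition and a log of the applied
    overrides with their rationales recorded verbatim.
    """
    groups = [set(g) for g in partition]
    known = {x for g in groups for x in g}
    applied: list[dict] = []
    for lineage, action, rationale in overrides:
        if lineage not in known:
            raise KeyError(f"unknown lineage in override: {lineage!r}")
        if action == "split_out":
            src = next(g for g in groups if lineage in g)
            if len(src) == 1:
                warnings.warn(
                    f"split_out of already-singleton lineage {lineage!r} "
                    "is a no-op",
                    stacklevel=2,
                )
            else:
                src.remove(lineage)
                groups.append({lineage})
        elif action.startswith("merge_into:"):
            target = action.split(":", 1)[1]
            if target not in known:
                raise KeyError(f"unknown merge target: {target!r}")
            src = next(g for g in groups if lineage in g)
            dst = next(g for g in groups if target in g)
            if src is not dst:
                dst |= src
                groups.remove(src)
        else:
            raise ValueError(f"unknown override action: {action!r}")
        applied.append(
            {"lineage": lineage, "action": action, "rationale": rationale}
        )
    return _canonical(groups), applied


@dataclass(frozen=True)
class DelimitationResult:
    """Final grouping with per-lineage verdicts.

    ``status`` maps every lineage to CCS / UCS / DCL (lineages merged into
    a multi-lineage group are reported as one unit and share its verdict).
    """

    groups: Partition
    status: dict[str, str]
    overrides_applied: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, group in enumerate(self.groups, start=1):
            for lineage in group:
                rows.append(
                    {
                        "lineage": lineage,
                        "group": gi,
                        "group_members": "+".join(group),
                        "status": self.status[lineage],
                    }
                )
        return pd.DataFrame(rows).sort_values("lineage", ignore_index=True)

    def counts(self) -> dict[str, int]:
        """Verdict counts at the *group* level (one unit per group)."""
        out: dict[str, int] = {}
        for group in self.groups:
            s = self.status[group[0]]
            out[s] = out.get(s, 0) + 1
        return out


def integrate_evidence(
    partition: Partition, evidence: pd.DataFrame
) -> DelimitationResult:
    """Classify each genetically distinct group as CCS, UCS, or DCL.

    ``evidence`` has one row per lineage with columns ``lineage``,
    ``acoustic_status`` and ``morpho_status``, each in
    {distinct, not_distinct, unavailable}. A group is CCS if any member has
    a distinct acoustic or morphological status; UCS if all such evidence is
    unavailable; DCL if some evidence is available but none distinct.
    """
    ev = evidence.set_index("lineage")
    for col in ("acoustic_status", "morpho_status"):
        bad = set(ev[col]) - VALID_STATUS
        if bad:
            raise ValueError(f"invalid {col} value(s): {sorted(bad)}")
    status: dict[str, str] = {}
    for group in partition:
        missing = [x for x in group if x not in ev.index]
        if missing:
            raise KeyError(f"lineage(s) missing from evidence: {missing}")
        acoustic = [ev.loc[x, "acoustic_status"] for x in group]
        morpho = [ev.loc[x, "morpho_status"] for x in group]
        statuses = acoustic + morpho
        if "distinct" in statuses:
            verdict = "CCS"
        elif all(s == "unavailable" for s in statuses):
            verdict = "UCS"
        else:
            verdict = "DCL"
        for x in group:
            status[x] = verdict
    return DelimitationResult(groups=partition, status=status)
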