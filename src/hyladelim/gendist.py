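"""Uncorrected p-distances and clade-level divergence summaries.

The genetic stage of the delimitation protocol: pairwise uncorrected
p-distances on an aligned mitochondrial marker (typically 16S), aggregated
within and between named mtDNA clades, and binned into the verbal
divergence categories used for candidate-species screening (low < 3%,
moderate 3–5%, high > 5%, very high > 7%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "DivergenceCategory",
    "read_alignment",
    "read_clade_map",
    "pairwise_p_distance",
    "clade_pair_summary",
    "classify_divergence",
    "summary_matrix",
]

#: sites with fewer than this many pairwise-compared positions are suspect
#: (short fragments inflate or deflate distances; cf. a 506 bp 16S fragment
#: producing an artifactually low inter-clade distance)
MIN_COMPARED_SITES = 200

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


@dataclass(frozen=True)
class Alignment:
    """Aligned sequences over {A,C,G,T,-,N} (case-insensitive).

    ``codes`` holds the alignment as a (n_seqs, n_sites) uint8 array with
    A,C,G,T -> 0..3 and everything else (gaps, N, other ambiguity codes)
    -> 255, i.e. excluded from comparisons.
    """

    ids: tuple[str, ...]
    codes: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.ids):
            raise ValueError("codes must be (n_seqs, n_sites)")

    @classmethod
    def from_records(cls, records: list[tuple[str, str]]) -> "Alignment":
        if not records:
            raise ValueError("empty alignment")
        lengths = {len(seq) for _, seq in records}
        if len(lengths) != 1:
            raise ValueError(
                f"sequences have unequal lengths {sorted(lengths)}; "
                "input must be aligned"
            )
        ids = tuple(sid for sid, _ in records)
        arr = np.frombuffer(
            "".join(seq for _, seq in records).encode("ascii"), dtype=np.uint8
        ).reshape(len(records), -1)
        return cls(ids=ids, codes=_CODE[arr])

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return Alignment.from_records(records)


def read_clade_map(path: str | Path) -> dict[str, str]:
    """Read a two-column delimited id → clade file (header optional)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"clade map {path} needs two columns (id, clade)")
    cols = list(df.columns[:2])
    if cols != ["id", "clade"] and not set(df.columns) >= {"id", "clade"}:
        # headerless file: first row was data
        df = pd.read_csv(path, sep=None, engine="python", header=None)
        cols = [0, 1]
    return dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise p-distances with per-cell compared-site counts.

    ``values[i, j]`` is mismatches / compared sites for the pair, computed
    under pairwise deletion (a site counts iff both characters are
    unambiguous bases). Pairs with zero compared sites are NaN and flagged
    by ``counts[i, j] == 0``.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def pairwise_p_distance(aln: Alignment) -> DistanceMatrix:
    """Pairwise uncorrected p-distances with pairwise deletion of gaps/N."""
    if aln.n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    n = aln.n_seqs
    valid = aln.codes != 255
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    short_pairs = 0
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diff = (aln.codes[i] != aln.codes[i + 1 :]) & both
        c = both.sum(axis=1)
        m = diff.sum(axis=1)
        counts[i, i + 1 :] = counts[i + 1 :, i] = c
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(c > 0, m / np.maximum(c, 1), np.nan)
        values[i, i + 1 :] = values[i + 1 :, i] = d
        short_pairs += int(((c > 0) & (c < MIN_COMPARED_SITES)).sum())
    counts[np.diag_indices(n)] = valid.sum(axis=1)
    if np.any((counts == 0) & ~np.eye(n, dtype=bool)):
        warnings.warn(
            "some sequence pairs share zero compared sites; "
            "their distances are reported as missing (NaN)",
            stacklevel=2,
        )
    if short_pairs:
        warnings.warn(
            f"{short_pairs} sequence pair(s) share fewer than "
            f"{MIN_COMPARED_SITES} compared sites; distances for short "
            "fragments can be artifactual",
            stacklevel=2,
        )
    return DistanceMatrix(ids=aln.ids, values=values, counts=counts)


def clade_pair_summary(
    dm: DistanceMatrix, clade_map: dict[str, str]
) -> pd.DataFrame:
    """Aggregate pairwise distances within and between clades.

    Returns a long-format table with one row per unordered clade pair (and
    each clade with itself, when it has >= 2 members): columns ``clade_a``,
    ``clade_b``, ``mean``, ``sd``, ``min``, ``max``, ``n_comparisons``.
    ``n_comparisons`` counts sequence pairs. SD is the sample SD (n-1) and
    is NaN for a single comparison.
    """
    missing = [sid for sid in dm.ids if sid not in clade_map]
    if missing:
        raise KeyError(
            f"sequence ids missing from the clade assignment: {missing[:5]}"
        )
    clades = sorted(set(clade_map[sid] for sid in dm.ids))
    members = {
        c: [i for i, sid in enumerate(dm.ids) if clade_map[sid] == c]
        for c in clades
    }
    rows = []
    for a_idx, a in enumerate(clades):
        for b in clades[a_idx:]:
            if a == b:
                idx = members[a]
                if len(idx) < 2:
                    continue  # singleton clade: no intra entry
                vals = [
                    dm.values[i, j]
                    for k, i in enumerate(idx)
                    for j in idx[k + 1 :]
                ]
            else:
                vals = [
                    dm.values[i, j] for i in members[a] for j in members[b]
                ]
            arr = np.asarray(vals, dtype=float)
            arr = arr[~np.isnan(arr)]
            if arr.size == 0:
                raise ValueError(
                    f"no usable distances for clade pair ({a}, {b})"
                )
            rows.append(
                {
                    "clade_a": a,
                    "clade_b": b,
                    "mean": float(arr.mean()),
                    "sd": float(arr.std(ddof=1)) if arr.size > 1 else np.nan,
                    "min": float(arr.min()),
                    "max": float(arr.max()),
                    "n_comparisons": int(arr.size),
                }
            )
    return pd.DataFrame(rows)


class DivergenceCategory(str, Enum):
    """Verbal divergence bins used for candidate-species screening."""

    low = "low"
    moderate = "moderate"
    high = "high"
    very_high = "very_high"


def classify_divergence(p: float) -> DivergenceCategory:
    """Bin a p-distance: [0, 0.03) low, [0.03, 0.05] moderate,
    (0.05, 0.07] high, (0.07, 1] very_high.

    The candidate-species threshold itself is strict (> 3.0%); the verbal
    bins overlap at their printed edges, so boundaries are fixed half-open
    as above.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p-distance must be in [0, 1], got {p!r}")
    if p < 0.03:
        return DivergenceCategory.low
    if p <= 0.05:
        return DivergenceCategory.moderate
    if p <= 0.07:
        return DivergenceCategory.high
    return DivergenceCategory.very_high


def summary_matrix(summary: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long summary into the classic publication layout: clade ×
    clade with inter-clade means below the diagonal, sequence-pair counts
    above, and intra-clade means on the diagonal (NaN for singletons)."""
    clades = sorted(set(summary["clade_a"]) | set(summary["clade_b"]))
    out = pd.DataFrame(np.nan, index=clades, columns=clades)
    for _, row in summary.iterrows():
        a, b = row["clade_a"], row["clade_b"]
        if a == b:
            out.loc[a, a] = row["mean"]
        else:
            lo, hi = sorted([a, b])
            out.loc[hi, lo] = row["mean"]  # below diagonal
            out.loc[lo, hi] = row["n_comparisons"]  # above diagonal
    return out
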