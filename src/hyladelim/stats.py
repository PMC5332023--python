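"""Call-variable PCA, Welch t-tests, and group summary tables.

The acoustic-space comparison runs a correlation-matrix PCA on five Type I
note variables (duration, pulse count, rise time, bandwidth, dominant
frequency), retains components with eigenvalue > 1, and compares groups of
males with Welch (unequal-variance) t-tests on the retained scores. Welch
tests can also be computed directly from printed summary statistics
(mean, SD, n per group), which is how published morphometric tables are
re-checked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PCA_VARIABLES",
    "PCAResult",
    "correlation_pca",
    "welch_from_summary",
    "welch_from_samples",
    "pc_group_tests",
    "summarize_groups",
]

#: the five Type I advertisement-call variables entering the PCA
PCA_VARIABLES = [
    "typeI_duration_s",
    "n_pulses_typeI",
    "rise_time_typeI_s",
    "freq_bandwidth_hz",
    "dominant_freq_hz",
]


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA output.

    Eigenvalues sum to the number of variables; percent variance is
    eigenvalue / n_variables * 100. ``loadings`` (variables x components)
    and ``eigenvalues`` cover *all* components; ``scores`` only the
    retained ones (eigenvalue > 1). Sign convention: the largest-magnitude
    entry of each loading column is positive.
    """

    variables: tuple[str, ...]
    loadings: np.ndarray
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    n_retained: int
    scores: np.ndarray
    groups: tuple | None = None

    def loadings_table(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(len(self.eigenvalues))]
        df = pd.DataFrame(self.loadings, index=self.variables, columns=cols)
        df.loc["eigenvalue"] = self.eigenvalues
        df.loc["percent_variance"] = self.percent_variance
        return df


def correlation_pca(
    fm: pd.DataFrame, group_col: str = "group"
) -> PCAResult:
    """PCA on the correlation matrix of the call-variable matrix.

    ``fm`` has one row per male (per-individual averages over their calls),
    the five variables in :data:`PCA_VARIABLES` (or any numeric columns),
    and optionally a group-label column. Components with eigenvalue
    strictly > 1.0 are retained.
    """
    groups = None
    if group_col in fm.columns:
        groups = tuple(fm[group_col])
        fm = fm.drop(columns=[group_col])
    fm = fm.astype(float)
    if fm.isna().any().any():
        raise ValueError("feature matrix has missing cells")
    if len(fm) < 3:
        raise ValueError("need at least 3 rows for a PCA")
    sd = fm.std(ddof=1)
    zero = list(sd.index[sd == 0])
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    z = (fm - fm.mean()) / sd
    corr = np.corrcoef(z.values, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # sign convention: largest-|loading| entry positive
    for j in range(eigvec.shape[1]):
        k = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    n_retained = int(np.sum(eigval > 1.0))
    scores = z.values @ eigvec[:, :n_retained]
    p = corr.shape[0]
    return PCAResult(
        variables=tuple(fm.columns),
        loadings=eigvec,
        eigenvalues=eigval,
        percent_variance=eigval / p * 100.0,
        n_retained=n_retained,
        scores=scores,
        groups=groups,
    )


def welch_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float, float]:
    """Welch two-sample t-test from summary statistics.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2); df by Welch–Satterthwaite;
    two-sided p from the t distribution. For table display round df to the
    nearest integer.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
        raise ValueError("SDs must be >= 0 and not both zero")
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_from_samples(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float, float]:
    """Welch test from raw samples via their summary statistics; agrees
    with :func:`scipy.stats.ttest_ind(equal_var=False)` to machine
    precision."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    return welch_from_summary(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def pc_group_tests(
    pca: PCAResult,
    groups: tuple | list | None = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Pairwise Welch t-tests between groups on every retained PC score.

    No multiplicity correction by default; ``holm=True`` adds
    Holm-adjusted p-values. Groups with fewer than 2 members are skipped
    with a warning.
    """
    labels = np.asarray(groups if groups is not None else pca.groups)
    if labels is None or labels.size != pca.scores.shape[0]:
        raise ValueError("group labels must match the score rows")
    uniq = sorted(set(labels))
    usable = []
    for g in uniq:
        if np.sum(labels == g) < 2:
            warnings.warn(f"group {g!r} has < 2 members; skipped", stacklevel=2)
        else:
            usable.append(g)
    rows = []
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            for pc in range(pca.n_retained):
                xa = pca.scores[labels == a, pc]
                xb = pca.scores[labels == b, pc]
                t, df, p = welch_from_samples(xa, xb)
                rows.append(
                    {
                        "group_a": a,
                        "group_b": b,
                        "pc": pc + 1,
                        "t": t,
                        "df": df,
                        "p": p,
                    }
                )
    out = pd.DataFrame(
        rows, columns=["group_a", "group_b", "pc", "t", "df", "p"]
    )
    if holm and len(out):
        order = np.argsort(out["p"].values)
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].values[idx])
            adj[idx] = min(1.0, running)
        out["p_holm"] = adj
    return out


def summarize_groups(
    values: np.ndarray | list, groups: np.ndarray | list
) -> pd.DataFrame:
    """Per-group n / mean / SD / min / max (sample SD, n-1; SD is NaN for
    singleton groups). Empty groups are omitted with a warning."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise ValueError("every value needs a group label")
    rows = []
    for g in sorted(set(groups)):
        x = values[groups == g]
        x = x[~np.isnan(x)]
        if x.size == 0:
            warnings.warn(f"group {g!r} is empty; omitted", stacklevel=2)
            continue
        rows.append(
            {
                "group": g,
                "n": int(x.size),
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)) if x.size > 1 else np.nan,
                "min": float(x.min()),
                "max": float(x.max()),
            }
        )
    return pd.DataFrame(rows)
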