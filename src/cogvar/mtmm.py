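"""Convergent and discriminant validity: correlogram and the
multitrait-multimethod (MTMM) matrix.

The MTMM matrix covers nine raw tests spanning three theoretical
domains.  Its diagonal is a one-way random-effects intraclass
correlation (the share of total variance attributable to stable
between-subject differences); off-diagonal cells are repeated-measures
correlations, which estimate the within-subject association between two
tests after removing between-subject mean differences.  Cells are
annotated as same-test or same-domain according to the theoretical
composite memberships.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg

__all__ = [
    "MTMM_TESTS",
    "MTMM_DOMAINS",
    "MTMMMatrix",
    "icc",
    "rmcorr",
    "correlogram",
    "mtmm_matrix",
]

#: the nine raw tests of the MTMM matrix, in display order
MTMM_TESTS = [
    "avlt_total", "avlt_delayed", "lm_i", "lm_ii",
    "bvmt_total", "bvmt_delayed", "tmt_b", "stroop", "digsym",
]

#: theoretical-domain membership used for same-domain annotation
MTMM_DOMAINS = {
    "avlt_total": "imm", "lm_i": "imm", "bvmt_total": "imm",
    "avlt_delayed": "del", "lm_ii": "del", "bvmt_delayed": "del",
    "tmt_b": "exec", "stroop": "exec", "digsym": "exec",
}

#: same-test pairs (immediate/delayed forms of one instrument)
SAME_TEST_PAIRS = frozenset({
    frozenset({"avlt_total", "avlt_delayed"}),
    frozenset({"lm_i", "lm_ii"}),
    frozenset({"bvmt_total", "bvmt_delayed"}),
})


def icc(values: pd.Series | np.ndarray, subject_ids) -> float:
    """One-way random-effects intraclass correlation.

    ``sigma2_between / (sigma2_between + sigma2_within)`` from ANOVA
    mean squares, using the standard average group size
    ``k0 = (N - sum(n_i^2)/N) / (a - 1)`` for unbalanced designs.
    Negative variance estimates are truncated at zero.
    """
    frame = pd.DataFrame({
        "subject_id": np.asarray(subject_ids),
        "y": np.asarray(values, dtype=float),
    }).dropna()
    frame = frame.groupby("subject_id").filter(lambda g: len(g) >= 2)
    if frame["subject_id"].nunique() < 2:
        raise ValueError("ICC needs >= 2 subjects with >= 2 visits")
    y = frame["y"].to_numpy()
    groups = frame["subject_id"].to_numpy()
    n_total = y.size
    labels, counts = np.unique(groups, return_counts=True)
    a = labels.size
    grand = y.mean()
    means = frame.groupby("subject_id")["y"].mean()
    ss_between = float((counts * (means.loc[labels].to_numpy() - grand) ** 2).sum())
    ss_within = float(((y - means.loc[groups].to_numpy()) ** 2).sum())
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (n_total - a)
    k0 = (n_total - (counts ** 2).sum() / n_total) / (a - 1)
    var_between = max((ms_between - ms_within) / k0, 0.0)
    return var_between / (var_between + ms_within)


def rmcorr(
    x: pd.Series | np.ndarray, y: pd.Series | np.ndarray, subject_ids,
) -> tuple[float, int]:
    """Repeated-measures correlation (ANCOVA with subject factor and a
    common slope); returns ``(r_rm, dof)`` with
    ``dof = N_obs - N_subjects - 1``."""
    frame = pd.DataFrame({
        "subject_id": np.asarray(subject_ids),
        "x": np.asarray(x, dtype=float),
        "y": np.asarray(y, dtype=float),
    }).dropna()
    frame = frame.groupby("subject_id").filter(lambda g: len(g) >= 2)
    if frame["subject_id"].nunique() < 3:
        raise ValueError("rmcorr needs >= 3 subjects with >= 2 paired visits")
    out = pg.rm_corr(data=frame, x="x", y="y", subject="subject_id")
    return float(out["r"].iloc[0]), int(out["dof"].iloc[0])


def correlogram(
    scores: pd.DataFrame, outcomes: list[str],
    method: str = "spearman", subject_means: bool = False,
) -> pd.DataFrame:
    """Pairwise Spearman correlations over person-visits (default) or
    over subject means; symmetric with unit diagonal."""
    data = scores[["subject_id"] + outcomes] if subject_means else scores[outcomes]
    if subject_means:
        data = data.groupby(scores["subject_id"]).mean()[outcomes]
    corr = data.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class MTMMMatrix:
    values: pd.DataFrame        # square: ICC diagonal, rmcorr off-diagonal
    dof: pd.DataFrame           # rmcorr dof off-diagonal (0 on diagonal)
    same_test: pd.DataFrame     # boolean annotation
    same_domain: pd.DataFrame   # boolean annotation

    def to_csv(self, path: str) -> None:
        self.values.to_csv(path)


def mtmm_matrix(
    scores: pd.DataFrame, tests: list[str] | None = None,
    domain_map: dict[str, str] | None = None,
) -> MTMMMatrix:
    """Assemble the MTMM matrix from a ScoreMatrix with ``subject_id``."""
    tests = tests or MTMM_TESTS
    domain_map = domain_map or MTMM_DOMAINS
    missing = [t for t in tests if t not in scores.columns]
    if missing:
        raise KeyError(f"missing test columns: {missing}")
    k = len(tests)
    vals = np.full((k, k), np.nan)
    dof = np.zeros((k, k), dtype=int)
    subj = scores["subject_id"]
    for i, t in enumerate(tests):
        vals[i, i] = icc(scores[t], subj)
    for i in range(k):
        for j in range(i + 1, k):
            r, d = rmcorr(scores[tests[i]], scores[tests[j]], subj)
            vals[i, j] = vals[j, i] = r
            dof[i, j] = dof[j, i] = d
    same_test = np.zeros((k, k), dtype=bool)
    same_domain = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(k):
            if i == j:
                same_test[i, j] = True
                same_domain[i, j] = True
                continue
            pair = frozenset({tests[i], tests[j]})
            same_test[i, j] = pair in SAME_TEST_PAIRS
            same_domain[i, j] = domain_map[tests[i]] == domain_map[tests[j]]
    idx = pd.Index(tests)
    return MTMMMatrix(
        values=pd.DataFrame(vals, index=idx, columns=idx),
        dof=pd.DataFrame(dof, index=idx, columns=idx),
        same_test=pd.DataFrame(same_test, index=idx, columns=idx),
        same_domain=pd.DataFrame(same_domain, index=idx, columns=idx),
    )
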