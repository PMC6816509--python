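"""Score standardization and composite construction.

Raw scores are z-scored against a standardizing sample (pooled over its
person-visits), with timed tests (TMT-A, TMT-B) sign-flipped so that
higher always means better.  Composites are weighted averages of
z-scores, restandardized to mean 0 / SD 1 on the standardizing sample.
The registry holds the thirteen standard composites: five empirically
weighted domain composites (EMP), three equally weighted theoretical
domain composites (THEO), and five global PACC variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import KEY_COLUMNS, RAW_SCORES, SCORE_COLUMNS

__all__ = [
    "LOWER_BETTER",
    "COMPOSITE_NAMES",
    "OUTCOME_COLUMNS",
    "DegenerateScaleError",
    "StandardizationParams",
    "CompositeDefinition",
    "standardize",
    "apply_standardization",
    "build_composite",
    "add_composites",
    "table2_registry",
    "registry_to_yaml",
    "registry_from_yaml",
]

#: raw scores where a lower native value means better performance
LOWER_BETTER = frozenset({"tmt_a", "tmt_b"})

COMPOSITE_NAMES = [
    "EMP-IMM-LRN", "EMP-DEL-REC", "EMP-LM", "EMP-BVMT", "EMP-EXEC-FN",
    "THEO-IMM-LRN", "THEO-DEL-REC", "THEO-EXEC-FN",
    "PACC4-MMSE", "PACC3", "PACC4-CFL", "PACC4-TMTB", "PACC3-TMTB",
]

#: the 25 analysed outcomes: 12 raw z-scores + 13 composites
OUTCOME_COLUMNS = RAW_SCORES + COMPOSITE_NAMES


class DegenerateScaleError(ValueError):
    """A score column is constant on the standardizing sample."""


@dataclass
class StandardizationParams:
    """Per-score moments and direction multipliers used for z-scoring."""

    means: dict[str, float]
    sds: dict[str, float]
    directions: dict[str, int]
    composite_means: dict[str, float] = field(default_factory=dict)
    composite_sds: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "means": self.means, "sds": self.sds,
            "directions": self.directions,
            "composite_means": self.composite_means,
            "composite_sds": self.composite_sds,
        }


@dataclass
class CompositeDefinition:
    name: str
    components: list[tuple[str, float]]  # (score column, weight)
    weight_scheme: str = "equal"         # "equal" | "empirical"

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError(f"composite {self.name} has no components")
        weights = np.array([w for _, w in self.components], dtype=float)
        if not np.all(np.isfinite(weights)) or np.all(weights == 0):
            raise ValueError(f"composite {self.name} has invalid weights")
        if self.weight_scheme == "equal" and len(set(weights)) > 1:
            raise ValueError(
                f"composite {self.name}: equal scheme requires identical weights"
            )


# ----------------------------------------------------------------------
def standardize(
    table: pd.DataFrame,
    sample: pd.Series | np.ndarray | None = None,
    score_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Z-score the score columns of ``table``.

    ``sample`` is a boolean person-visit selector defining the
    standardizing sample whose pooled mean/SD are used; by default all
    rows.  Returns a ScoreMatrix (keys + z columns) and the params, so
    held-out rows can later be scored with :func:`apply_standardization`.
    """
    cols = score_columns or [c for c in SCORE_COLUMNS if c in table.columns]
    mask = (np.ones(len(table), dtype=bool) if sample is None
            else np.asarray(sample, dtype=bool))
    if mask.sum() < 2:
        raise ValueError("standardizing sample needs >= 2 person-visits")
    means, sds, dirs = {}, {}, {}
    for c in cols:
        x = table.loc[mask, c].to_numpy(dtype=float)
        m, s = float(np.mean(x)), float(np.std(x, ddof=1))
        if s == 0.0 or not np.isfinite(s):
            raise DegenerateScaleError(
                f"score column {c!r} is constant on the standardizing sample"
            )
        means[c], sds[c] = m, s
        dirs[c] = -1 if c in LOWER_BETTER else 1
    params = StandardizationParams(means, sds, dirs)
    return apply_standardization(table, params, cols), params


def apply_standardization(
    table: pd.DataFrame,
    params: StandardizationParams,
    score_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Score rows (possibly held out) with existing standardization params."""
    cols = score_columns or list(params.means)
    keys = [c for c in KEY_COLUMNS + ["age_at_visit"] if c in table.columns]
    out = table[keys].copy()
    for c in cols:
        out[c] = (params.directions[c]
                  * (table[c].astype(float) - params.means[c]) / params.sds[c])
    return out


# ----------------------------------------------------------------------
def build_composite(
    z: pd.DataFrame,
    cdef: CompositeDefinition,
    standardizing_mask: np.ndarray | None = None,
    params: StandardizationParams | None = None,
) -> pd.Series:
    """Weighted average of component z-scores, restandardized.

    The weighted average is ``sum(w_i z_i) / sum(w_i)`` (weights need
    not be normalized); rows missing any component are missing in the
    result.  Restandardization moments come from the standardizing
    rows, or from ``params.composite_*`` when already recorded (so
    held-out rows are scored on the standardizing sample's scale).
    """
    missing = [s for s, _ in cdef.components if s not in z.columns]
    if missing:
        raise KeyError(f"composite {cdef.name}: unknown components {missing}")
    comp_cols = z[[s for s, _ in cdef.components]].to_numpy(dtype=float)
    weights = np.array([w for _, w in cdef.components], dtype=float)
    raw = comp_cols @ weights / weights.sum()
    raw = pd.Series(raw, index=z.index, name=cdef.name)
    raw[np.any(~np.isfinite(comp_cols), axis=1)] = np.nan

    if params is not None and cdef.name in params.composite_means:
        m = params.composite_means[cdef.name]
        s = params.composite_sds[cdef.name]
    else:
        mask = (np.ones(len(z), dtype=bool) if standardizing_mask is None
                else np.asarray(standardizing_mask, dtype=bool))
        vals = raw[mask].dropna()
        m, s = float(vals.mean()), float(vals.std(ddof=1))
        if s == 0.0 or not np.isfinite(s):
            raise DegenerateScaleError(
                f"composite {cdef.name} is constant on the standardizing sample"
            )
        if params is not None:
            params.composite_means[cdef.name] = m
            params.composite_sds[cdef.name] = s
    return (raw - m) / s


def add_composites(
    z: pd.DataFrame,
    registry: list[CompositeDefinition],
    standardizing_mask: np.ndarray | None = None,
    params: StandardizationParams | None = None,
) -> pd.DataFrame:
    """Append every composite in ``registry`` to the ScoreMatrix."""
    out = z.copy()
    for cdef in registry:
        out[cdef.name] = build_composite(z, cdef, standardizing_mask, params)
    return out


# ----------------------------------------------------------------------
#: default empirical weights for the EMP composites.  The published
#: factor loadings behind the empirical composites are not public, so
#: these are synthetic stand-ins with the right structure (loadings in
#: (0, 1], per-factor test sets as in the registry); they are config
#: inputs and can be replaced.
DEFAULT_EMP_WEIGHTS: dict[str, dict[str, float]] = {
    "EMP-IMM-LRN": {"avlt_t12": 1.0},
    "EMP-DEL-REC": {"avlt_t35": 0.83, "avlt_delayed": 0.77},
    "EMP-LM": {"lm_i": 0.87, "lm_ii": 0.89},
    "EMP-BVMT": {"bvmt_total": 0.85, "bvmt_delayed": 0.83},
    "EMP-EXEC-FN": {"stroop": 0.78, "tmt_a": 0.65, "tmt_b": 0.81},
}

_THEO_MEMBERS: dict[str, list[str]] = {
    "THEO-IMM-LRN": ["avlt_total", "lm_i", "bvmt_total"],
    "THEO-DEL-REC": ["avlt_delayed", "lm_ii", "bvmt_delayed"],
    "THEO-EXEC-FN": ["stroop", "tmt_b", "digsym"],
    "PACC4-MMSE": ["avlt_total", "lm_ii", "digsym", "mmse"],
    "PACC3": ["avlt_total", "lm_ii", "digsym"],
    "PACC4-CFL": ["avlt_total", "lm_ii", "digsym", "cfl"],
    "PACC4-TMTB": ["avlt_total", "lm_ii", "tmt_b", "mmse"],
    "PACC3-TMTB": ["avlt_total", "lm_ii", "tmt_b"],
}


def table2_registry(
    emp_weights: dict[str, dict[str, float]] | None = None,
) -> list[CompositeDefinition]:
    """The thirteen standard composites.

    Empirical composites use the supplied (or default synthetic)
    weights; the AVLT contribution to the empirical immediate-learning
    and delayed-recall composites uses the trial 1-2 and trial 3-5
    subtotals respectively.  Theoretical and PACC composites use equal
    weights.
    """
    weights = emp_weights or DEFAULT_EMP_WEIGHTS
    defs = [
        CompositeDefinition(name, sorted(weights[name].items()),
                            weight_scheme="empirical")
        for name in COMPOSITE_NAMES[:5]
    ]
    defs += [
        CompositeDefinition(name, [(s, 1.0) for s in _THEO_MEMBERS[name]],
                            weight_scheme="equal")
        for name in COMPOSITE_NAMES[5:]
    ]
    return defs


def registry_to_yaml(registry: list[CompositeDefinition], path: str) -> None:
    data = [
        {"name": d.name, "weight_scheme": d.weight_scheme,
         "components": {s: float(w) for s, w in d.components}}
        for d in registry
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def registry_from_yaml(path: str) -> list[CompositeDefinition]:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return [
        CompositeDefinition(d["name"], list(d["components"].items()),
                            weight_scheme=d.get("weight_scheme", "equal"))
        for d in data
    ]
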