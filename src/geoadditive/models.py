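"""The six nested geo-additive models M0-M5 and DIC model comparison.

    M0: logit(p) = z'b                      (everything linear/fixed)
    M1: logit(p) = z'b + smooths
    M2: logit(p) = z'b + f_str + f_unstr    (continuous covariates linear)
    M3: logit(p) = z'b + smooths + f_str
    M4: logit(p) = z'b + smooths + f_unstr
    M5: logit(p) = z'b + smooths + f_str + f_unstr

Model comparison uses the deviance information criterion DIC = Dbar + p_D,
with Dbar the posterior mean deviance and p_D = Dbar - D(theta_bar) the
effective number of parameters, D evaluated at the posterior mean of the
linear predictor.  Differences below 3 leave models indistinguishable,
3-7 weakly distinguishable, above 7 clearly so; the smallest DIC wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import ChainResult, _deviance
from .records import CONTINUOUS_COVARIATES, Dataset, build_design
from .smooths import SmoothTerm, center_smooth, make_smooth_term
from .spatial import AdjacencyGraph

__all__ = ["MODEL_LEVELS", "ModelSpec", "DICResult", "build_model", "compute_dic", "delta_dic"]

MODEL_LEVELS = ("M0", "M1", "M2", "M3", "M4", "M5")

#: level -> (smooths active, structured, unstructured)
_LEVEL_TERMS = {
    "M0": (False, False, False),
    "M1": (True, False, False),
    "M2": (False, True, True),
    "M3": (True, True, False),
    "M4": (True, False, True),
    "M5": (True, True, True),
}


@dataclass
class ModelSpec:
    """One fully built model: data arrays + active term structure."""

    level: str
    outcome: str
    y: np.ndarray
    X_fixed: np.ndarray
    fixed_labels: list
    smooth_terms: list[SmoothTerm]
    structured: bool
    unstructured: bool
    graph: AdjacencyGraph | None
    district_positions: np.ndarray | None
    meta: dict = field(default_factory=dict)


def build_model(
    level: str,
    dataset: Dataset,
    outcome: str,
    fixed_covariates,
    graph: AdjacencyGraph | None = None,
    smooth_covariates=CONTINUOUS_COVARIATES,
    n_interior_knots: int = 20,
    degree: int = 3,
    penalty_order: int = 2,
    allow_disconnected: bool = False,
) -> ModelSpec:
    """Assemble the design for one model level on one derived outcome.

    Records whose outcome is missing are dropped here (per-outcome
    exclusion).  In M0 and M2 the continuous covariates enter as single
    linear columns of the fixed design; in the smooth levels they become
    centered P-spline terms.  Spatial levels require an adjacency graph; a
    disconnected graph is an error unless ``allow_disconnected`` (then each
    component is constrained separately).
    """
    if level not in _LEVEL_TERMS:
        raise ValueError(f"unknown model level {level!r}; expected one of {MODEL_LEVELS}")
    smooths_on, structured, unstructured = _LEVEL_TERMS[level]
    if (structured or unstructured) and graph is None:
        raise ValueError(f"model {level} needs a district adjacency graph/map")
    if structured and graph is not None and graph.n_components > 1 and not allow_disconnected:
        raise ValueError(
            f"district map has {graph.n_components} connected components; pass "
            "allow_disconnected=True to fit per-component constrained ICAR fields"
        )

    frame = dataset.frame.dropna(subset=[outcome])
    y = frame[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {outcome!r} must be 0/1 after exclusions")

    X, labels = build_design(frame, fixed_covariates)
    terms: list[SmoothTerm] = []
    if smooths_on:
        for cov in smooth_covariates:
            terms.append(
                center_smooth(
                    make_smooth_term(
                        cov, frame[cov].to_numpy(dtype=float), n_interior_knots, degree, penalty_order
                    )
                )
            )
    else:
        lin = [frame[cov].to_numpy(dtype=float) for cov in smooth_covariates]
        if lin:
            # center linear columns so the intercept keeps its interpretation
            L = np.column_stack(lin)
            X = np.hstack([X, L - L.mean(axis=0)])
            labels = labels + list(smooth_covariates)

    d = None
    if structured or unstructured:
        idx = {lab: i for i, lab in enumerate(graph.labels)}
        unknown = set(frame["district_id"]) - set(idx)
        if unknown:
            raise ValueError(f"records reference districts missing from the map: {sorted(unknown)!r}")
        d = frame["district_id"].map(idx).to_numpy(dtype=int)

    return ModelSpec(
        level=level,
        outcome=outcome,
        y=y,
        X_fixed=X,
        fixed_labels=labels,
        smooth_terms=terms,
        structured=structured,
        unstructured=unstructured,
        graph=graph if (structured or unstructured) else None,
        district_positions=d,
        meta={"n": len(y)},
    )


@dataclass(frozen=True)
class DICResult:
    """Deviance information criterion summary for one fitted model."""

    dbar: float  # posterior mean deviance
    d_at_mean: float  # deviance at the posterior-mean linear predictor
    p_d: float  # effective number of parameters
    dic: float

    def as_dict(self) -> dict:
        return {"dbar": self.dbar, "p_d": self.p_d, "dic": self.dic}


def compute_dic(chain: ChainResult) -> DICResult:
    """DIC = Dbar + p_D with p_D = Dbar - D(eta_bar).

    The plug-in deviance is evaluated at the posterior mean of the linear
    predictor (not at block-wise parameter means).  Negative p_D is kept but
    flagged — it signals a poorly behaved fit.
    """
    if chain.n_stored == 0:
        raise ValueError("empty chain: no stored draws")
    dbar = float(chain.deviance.mean())
    d_hat = _deviance(chain.y, chain.eta_mean)
    p_d = dbar - d_hat
    if p_d < 0:
        import logging

        logging.getLogger(__name__).warning("negative p_D = %.3f (unstable fit?)", p_d)
    return DICResult(dbar=dbar, d_at_mean=d_hat, p_d=p_d, dic=dbar + p_d)


def _delta_label(delta: float) -> str:
    if delta < 3.0:
        return "indistinguishable"
    if delta <= 7.0:
        return "weak"
    return "clear"


def delta_dic(results: dict, reference: str | None = None) -> pd.DataFrame:
    """Delta-DIC comparison table across model levels.

    ``results`` maps level -> DICResult (or a bare DIC float).  The reference
    defaults to the smallest-DIC model (deterministic tie-break by level
    order); Delta = DIC(level) - DIC(reference).  Labels: < 3
    indistinguishable, 3-7 weak, > 7 clear.
    """
    if not results:
        raise ValueError("no DIC results to compare")
    dic_of = {
        lv: (r.dic if isinstance(r, DICResult) else float(r)) for lv, r in results.items()
    }
    if reference is None:
        reference = min(sorted(dic_of), key=lambda lv: dic_of[lv])
    if reference not in dic_of:
        raise ValueError(f"reference level {reference!r} not among results")
    rows = []
    for lv in sorted(dic_of):
        r = results[lv]
        delta = dic_of[lv] - dic_of[reference]
        rows.append(
            {
                "model": lv,
                "dbar": r.dbar if isinstance(r, DICResult) else np.nan,
                "p_d": r.p_d if isinstance(r, DICResult) else np.nan,
                "dic": dic_of[lv],
                "delta_dic": delta,
                "label": "Reference" if lv == reference else _delta_label(delta),
            }
        )
    out = pd.DataFrame(rows).sort_values("dic", kind="stable").reset_index(drop=True)
    return out
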