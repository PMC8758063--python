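"""Synthetic district maps and survey data with known generative truth.

The generator runs the full geo-additive model generatively: covariates are
drawn from configured marginals, the linear predictor is assembled as

    eta = intercept + z'b + f_age(age) + f_bmi(bmi) + f_wealth(wealth)
          + f_structured(district) + f_unstructured(district),

with f_structured from the sum-to-zero-constrained intrinsic CAR prior on a
connected polygon lattice and f_unstructured i.i.d. Gaussian, and the binary
outcome drawn Bernoulli(logit^-1(eta)).  Biomarkers (random glucose, three
blood-pressure readings, medication flag) are then back-filled consistently
with the operational classification rules, so the records module is
exercised end-to-end.  Back-filling is deterministic given the seed and is
not physiological — it exists to drive the classification code.

Default truth shapes mirror the study setting: low prevalence (~6% diabetes,
~16% hypertension), a near-linear increasing age effect, a mildly nonlinear
BMI effect, and an inverted-U wealth effect peaking mid-range.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from shapely.geometry import box

from .records import DEFAULT_CODING, Dataset, derive_outcomes
from .spatial import AdjacencyGraph, sample_icar

__all__ = [
    "GeneratorTruth",
    "SimulationResult",
    "default_truth",
    "ne_india_truth",
    "make_lattice_map",
    "simulate_dataset",
    "truth_report",
    "load_truth",
    "eval_truth_smooth",
    "write_records_csv",
]

# standardisation constants for the continuous covariates
_AGE_LOC, _AGE_SCALE = 32.0, 34.0 / np.sqrt(12.0)  # uniform(15, 49)
_BMI_LOC, _BMI_SCALE = 22.5, 4.0
_W_LOC, _W_SCALE = 0.0, 1.0


@dataclass
class GeneratorTruth:
    """Everything needed to regenerate a synthetic survey exactly.

    Smooth truths are polynomials in the standardised covariate,
    f(x) = sum_m coefs[m-1] * xs^m - center, with ``center`` chosen so the
    function has (numerically) mean zero under the covariate's sampling
    distribution.
    """

    intercept: float
    fixed_effects: dict  # covariate -> {level: log-odds coef}
    categorical_freqs: dict  # covariate -> {level: probability}
    smooths: dict  # name -> {"loc","scale","coefs","center"}
    tau2_str: float
    tau2_unstr: float
    rows: int
    cols: int
    n_keep: int | None
    n: int
    outcome: str = "hypertension"
    district_probs: list | None = None  # None = uniform across districts

    @property
    def n_districts(self) -> int:
        return self.n_keep if self.n_keep is not None else self.rows * self.cols


def eval_truth_smooth(truth: GeneratorTruth, name: str, x) -> np.ndarray:
    spec = truth.smooths[name]
    xs = (np.asarray(x, dtype=float) - spec["loc"]) / spec["scale"]
    out = np.zeros_like(xs)
    for m, c in enumerate(spec["coefs"], start=1):
        out += c * xs**m
    return out - spec["center"]


def _centered_poly(loc, scale, coefs, sampler) -> dict:
    """Fix the centering constant by quadrature over the sampling distribution."""
    q = sampler(np.linspace(0.0005, 0.9995, 4001))
    xs = (q - loc) / scale
    val = sum(c * xs**m for m, c in enumerate(coefs, start=1))
    return {"loc": loc, "scale": scale, "coefs": list(coefs), "center": float(val.mean())}


def _age_q(u):
    return 15.0 + 34.0 * u


def _bmi_q(u):
    from scipy.stats import truncnorm

    a, b_ = (14.0 - _BMI_LOC) / _BMI_SCALE, (45.0 - _BMI_LOC) / _BMI_SCALE
    return truncnorm.ppf(u, a, b_, loc=_BMI_LOC, scale=_BMI_SCALE)


def _wealth_q(u):
    from scipy.stats import truncnorm

    return truncnorm.ppf(u, -3.0, 3.0, loc=_W_LOC, scale=_W_SCALE)


_DEFAULT_FREQS = {
    "sex": {"Female": 0.6, "Male": 0.4},
    "residence": {"Rural": 0.7, "Urban": 0.3},
    "marital_status": {"Never married": 0.3, "Married": 0.6, "Widowed/Divorced/Separated": 0.1},
    "caste": {"Scheduled tribe": 0.45, "Scheduled caste": 0.15, "Others": 0.4},
    "education": {"Illiterate": 0.2, "Primary": 0.2, "Secondary": 0.4, "Higher secondary": 0.2},
    "consume_milk": {"No": 0.35, "Yes": 0.65},
    "consume_pulses": {"No": 0.1, "Yes": 0.9},
    "consume_vegetables": {"No": 0.05, "Yes": 0.95},
    "eat_fruits": {"No": 0.3, "Yes": 0.7},
    "consume_egg": {"No": 0.25, "Yes": 0.75},
    "eat_fish": {"No": 0.2, "Yes": 0.8},
    "eat_chicken": {"No": 0.3, "Yes": 0.7},
    "eat_fried_food": {"No": 0.3, "Yes": 0.7},
    "take_aerated_drinks": {"No": 0.5, "Yes": 0.5},
    "consume_alcohol": {"No": 0.8, "Yes": 0.2},
    "smoke_cigarettes": {"No": 0.85, "Yes": 0.15},
    "consume_tobacco": {"No": 0.75, "Yes": 0.25},
}

_DEFAULT_EFFECTS = {
    "sex": {"Male": 0.3},
    "residence": {"Urban": 0.15},
    "marital_status": {"Married": -0.2, "Widowed/Divorced/Separated": 0.25},
    "education": {"Primary": 0.1, "Secondary": -0.15, "Higher secondary": -0.2},
    "smoke_cigarettes": {"Yes": 0.3},
    "consume_alcohol": {"Yes": 0.2},
}


def default_truth(
    n: int = 4000,
    rows: int = 5,
    cols: int = 5,
    tau2_str: float = 0.25,
    tau2_unstr: float = 0.1,
    outcome: str = "hypertension",
    prevalence: float | None = None,
) -> GeneratorTruth:
    """The standard test-scale truth: 5x5 lattice, n=4000, M5 structure."""
    if prevalence is None:
        prevalence = 0.16 if outcome == "hypertension" else 0.06
    smooths = {
        "age": _centered_poly(_AGE_LOC, _AGE_SCALE, [0.25], _age_q),
        "bmi": _centered_poly(_BMI_LOC, _BMI_SCALE, [0.25, 0.12], _bmi_q),
        "wealth_score": _centered_poly(_W_LOC, _W_SCALE, [0.0, -0.3], _wealth_q),
    }
    return GeneratorTruth(
        intercept=float(logit(prevalence)),
        fixed_effects={k: dict(v) for k, v in _DEFAULT_EFFECTS.items()},
        categorical_freqs={k: dict(v) for k, v in _DEFAULT_FREQS.items()},
        smooths=smooths,
        tau2_str=tau2_str,
        tau2_unstr=tau2_unstr,
        rows=rows,
        cols=cols,
        n_keep=None,
        n=n,
        outcome=outcome,
    )


def ne_india_truth(n: int = 20000, seed: int = 20160101, **kwargs) -> GeneratorTruth:
    """An 82-district preset with uneven district sizes, mimicking the uneven
    cluster allocation of a DHS-style survey (9x10 lattice trimmed to 82
    connected cells)."""
    truth = replace(default_truth(n=n, **kwargs), rows=9, cols=10, n_keep=82)
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.full(truth.n_districts, 2.0))
    return replace(truth, district_probs=[float(x) for x in w])


def make_lattice_map(rows: int, cols: int, n_keep: int | None = None):
    """Unit-square lattice districts labelled 1..S with rook adjacency.

    Cells are taken in boustrophedon order (alternating row direction), so
    any prefix ``n_keep`` of them stays connected.  Returns
    ``(polygons, graph)`` with integer labels.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows, cols must be >= 1")
    cells = []
    for r in range(rows):
        cs = range(cols) if r % 2 == 0 else range(cols - 1, -1, -1)
        cells.extend((r, c) for c in cs)
    if n_keep is not None:
        cells = cells[:n_keep]
    pos = {rc: i for i, rc in enumerate(cells)}
    labels = list(range(1, len(cells) + 1))
    polygons = {lab: box(c, r, c + 1, r + 1) for lab, (r, c) in zip(labels, cells)}
    edges = []
    for (r, c), i in pos.items():
        for nb in ((r + 1, c), (r, c + 1)):
            if nb in pos:
                edges.append((i, pos[nb]))
    return polygons, AdjacencyGraph(labels=labels, edges=edges)


@dataclass
class SimulationResult:
    dataset: Dataset
    graph: AdjacencyGraph
    polygons: dict
    f_structured: np.ndarray
    f_unstructured: np.ndarray
    eta: np.ndarray
    truth: GeneratorTruth


def _true_eta(truth: GeneratorTruth, frame: pd.DataFrame, f_str, f_unstr, d) -> np.ndarray:
    eta = np.full(len(frame), truth.intercept)
    for cov, effs in truth.fixed_effects.items():
        for level, coef in effs.items():
            eta += coef * (frame[cov] == level).to_numpy(dtype=float)
    for name, col in (("age", "age"), ("bmi", "bmi"), ("wealth_score", "wealth_score")):
        if name in truth.smooths:
            eta += eval_truth_smooth(truth, name, frame[col].to_numpy())
    return eta + f_str[d] + f_unstr[d]


def _backfill_biomarkers(frame, y, outcome, rng):
    """Biomarkers consistent with the classification rules (non-physiological)."""
    n = len(frame)
    diab = y if outcome == "diabetes" else (rng.random(n) < 0.06).astype(float)
    htn = y if outcome == "hypertension" else (rng.random(n) < 0.16).astype(float)

    frame["glucose"] = np.where(
        diab == 1, rng.uniform(141.0, 320.0, n), rng.uniform(65.0, 140.0, n)
    ).round(1)

    meds = (htn == 1) & (rng.random(n) < 0.2)
    sbp_m = np.where(
        htn == 1,
        np.where(rng.random(n) < 0.7, rng.uniform(140.0, 185.0, n), rng.uniform(110.0, 139.0, n)),
        rng.uniform(95.0, 139.0, n),
    )
    # hypertensive via diastolic when systolic path not taken; else keep dbp low
    dbp_m = np.where(
        (htn == 1) & (sbp_m < 140.0) & ~meds,
        rng.uniform(90.0, 115.0, n),
        rng.uniform(60.0, 89.0, n),
    )
    sbp_m, dbp_m = sbp_m.round(1), dbp_m.round(1)
    spread = rng.uniform(0.0, 4.0, n).round(1)
    frame["sbp1"] = (sbp_m + rng.uniform(0.0, 25.0, n)).round(1)  # discarded reading
    frame["dbp1"] = (dbp_m + rng.uniform(0.0, 15.0, n)).round(1)
    frame["sbp2"], frame["sbp3"] = sbp_m + spread, sbp_m - spread
    frame["dbp2"], frame["dbp3"] = dbp_m + spread, dbp_m - spread
    frame["on_bp_medication"] = meds
    return frame


def simulate_dataset(truth: GeneratorTruth, seed: int) -> SimulationResult:
    """Generate one synthetic survey (same seed => byte-identical output)."""
    rng = np.random.default_rng(seed)
    polygons, graph = make_lattice_map(truth.rows, truth.cols, truth.n_keep)
    S, n = graph.n, truth.n

    f_str = sample_icar(graph, truth.tau2_str, rng) if truth.tau2_str > 0 else np.zeros(S)
    f_unstr = (
        np.sqrt(truth.tau2_unstr) * rng.standard_normal(S)
        if truth.tau2_unstr > 0
        else np.zeros(S)
    )

    probs = truth.district_probs if truth.district_probs is not None else np.full(S, 1.0 / S)
    d = rng.choice(S, size=n, p=probs)

    frame = pd.DataFrame(
        {
            "respondent_id": np.arange(1, n + 1),
            "district_id": np.asarray(graph.labels)[d],
            "age": rng.uniform(15.0, 49.0, n).round(2),
            "bmi": np.clip(rng.normal(_BMI_LOC, _BMI_SCALE, n), 14.0, 45.0).round(2),
            "wealth_score": np.clip(rng.normal(_W_LOC, _W_SCALE, n), -3.0, 3.0).round(4),
        }
    )
    for cov, freqs in truth.categorical_freqs.items():
        levels = list(freqs)
        frame[cov] = rng.choice(levels, size=n, p=np.array([freqs[l] for l in levels]))

    eta = _true_eta(truth, frame, f_str, f_unstr, d)
    y = (rng.random(n) < expit(eta)).astype(float)
    prev = float(y.mean())
    if not 0.005 < prev < 0.5:
        warnings.warn(
            f"simulated prevalence {100 * prev:.2f}% outside the realistic (0.5%, 50%) band",
            stacklevel=2,
        )

    frame = _backfill_biomarkers(frame, y, truth.outcome, rng)
    frame = derive_outcomes(frame)
    dataset = Dataset(frame=frame, district_index={lab: i for i, lab in enumerate(graph.labels)})
    return SimulationResult(
        dataset=dataset,
        graph=graph,
        polygons=polygons,
        f_structured=f_str,
        f_unstructured=f_unstr,
        eta=eta,
        truth=truth,
    )


def truth_report(truth: GeneratorTruth, path) -> str:
    """Serialise the truth to JSON; returns the file's sha256 for manifests."""
    payload = json.dumps(asdict(truth), indent=2, sort_keys=True)
    with open(path, "w") as fh:
        fh.write(payload)
    return hashlib.sha256(payload.encode()).hexdigest()


def load_truth(path) -> GeneratorTruth:
    with open(path) as fh:
        return GeneratorTruth(**json.load(fh))


def truth_fixed_vector(truth: GeneratorTruth, labels) -> dict:
    """True log-odds coefficient per fixed-design label ('cov=level' -> coef).

    Labels without a configured effect are truly zero; the intercept is
    omitted (it absorbs centering offsets and has no clean truth value).
    """
    out = {}
    for lab in labels:
        if "=" not in lab:
            continue
        cov, level = lab.split("=", 1)
        out[lab] = float(truth.fixed_effects.get(cov, {}).get(level, 0.0))
    return out


def write_records_csv(dataset: Dataset, path) -> None:
    cols = (
        ["respondent_id", "district_id", "age", "bmi", "wealth_score"]
        + list(DEFAULT_CODING.levels)
        + ["glucose", "sbp1", "dbp1", "sbp2", "dbp2", "sbp3", "dbp3", "on_bp_medication"]
    )
    dataset.frame[cols].to_csv(path, index=False)
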