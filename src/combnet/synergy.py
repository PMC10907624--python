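"""Synergy reference models (HSA, Bliss, Loewe, ZIP), combination ratio, DSS.

A drug-combination experiment measures an inhibition fraction y ∈ [0, 1] for
each drug alone along a dose ladder (monotherapy) and for every dose pair
(the combination grid). Each reference model predicts the combination
response expected if the drugs do not interact:

* HSA — the better single agent: max(y_a, y_b).
* Bliss — probabilistic independence: y_a + y_b − y_a·y_b.
* Loewe — dose additivity: the response y solving
  x_a/D_a(y) + x_b/D_b(y) = 1, where D(y) inverts the fitted Hill curve
  (a drug "combined with itself" scores exactly zero).
* ZIP — zero interaction potency: a Bliss-form expectation computed from
  fitted monotherapy Hill curves, compared against the combination surface
  smoothed by conditional Hill refits along each dose axis; the delta is
  averaged over the two fitting directions.

Synergy excess is observed − expected per combination cell; the summary
score is 100 × mean excess (percent-inhibition scale, positive = synergy).
The combination ratio CR = combo / max(single agents) flags added benefit at
CR > 1, and :func:`dss` is a normalized area under the monotherapy curve
above a 10% activity threshold (a drug-sensitivity score in [0, 100]).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "HillParams",
    "DoseResponseSurface",
    "SynergyResult",
    "fit_hill",
    "expected_response",
    "synergy_score",
    "combination_ratio",
    "dss",
    "read_combo_csv",
    "write_combo_csv",
]

MODELS = ("hsa", "bliss", "loewe", "zip")


@dataclass
class HillParams:
    """Four-parameter logistic dose–response curve on the fraction scale.

    y(x) = e_min + (e_max − e_min) / (1 + (ec50/x)^slope); y(0) = e_min.
    """

    e_min: float
    e_max: float
    ec50: float
    slope: float
    rmse: float = 0.0
    flagged: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.e_min <= self.e_max <= 1.0):
            raise ValueError("need 0 <= e_min <= e_max <= 1")
        if self.ec50 <= 0 or self.slope <= 0:
            raise ValueError("ec50 and slope must be positive")

    def __call__(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        y = np.where(
            x > 0,
            self.e_min
            + (self.e_max - self.e_min)
            / (1.0 + (self.ec50 / np.maximum(x, 1e-300)) ** self.slope),
            self.e_min,
        )
        return float(y) if y.ndim == 0 else y

    def inverse(self, y: float) -> float:
        """Dose D(y) producing response y; requires e_min < y < e_max."""
        if not (self.e_min < y < self.e_max):
            raise ValueError("response outside the open achievable range")
        r = (y - self.e_min) / (self.e_max - y)
        return self.ec50 * r ** (1.0 / self.slope)


@dataclass
class DoseResponseSurface:
    """Monotherapy rows/columns plus a combination grid on fixed dose ladders."""

    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    mono_a: np.ndarray
    mono_b: np.ndarray
    combo: np.ndarray  # shape (len(doses_a), len(doses_b))

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.mono_a = np.asarray(self.mono_a, dtype=float)
        self.mono_b = np.asarray(self.mono_b, dtype=float)
        self.combo = np.asarray(self.combo, dtype=float)
        for name, d in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if np.any(d <= 0) or np.any(np.diff(d) <= 0):
                raise ValueError(f"{name} must be strictly increasing and positive")
        if self.combo.shape != (self.doses_a.size, self.doses_b.size):
            raise ValueError("combo grid shape must match the dose ladders")
        for name, r in (
            ("mono_a", self.mono_a),
            ("mono_b", self.mono_b),
            ("combo", self.combo),
        ):
            if np.any(r < -1e-9) or np.any(r > 1 + 1e-9):
                raise ValueError(f"{name} responses must lie in [0, 1]")


@dataclass
class SynergyResult:
    model: str
    excess: np.ndarray  # observed − expected, fraction scale, per combo cell
    score: float  # 100 × mean excess
    expected: np.ndarray
    flags: list[str] = field(default_factory=list)


def fit_hill(doses, responses) -> HillParams:
    """Least-squares 4-parameter logistic fit with parameters bounded to the
    fraction scale; a poor fit (RMSE > 0.15) is flagged but not fatal."""
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.size < 4:
        raise ValueError("need at least 4 dose points to fit a Hill curve")
    if np.any(responses < -1e-9) or np.any(responses > 1 + 1e-9):
        raise ValueError("responses must lie in [0, 1]")
    responses = np.clip(responses, 0.0, 1.0)

    def f(x, e_min, e_max, log_ec50, slope):
        return e_min + (e_max - e_min) / (1.0 + (10.0**log_ec50 / x) ** slope)

    lo_d, hi_d = math.log10(doses.min()), math.log10(doses.max())
    p0 = [
        float(responses.min()),
        float(responses.max()),
        0.5 * (lo_d + hi_d),
        1.0,
    ]
    bounds = ([0.0, 0.0, lo_d - 3, 0.05], [1.0, 1.0, hi_d + 3, 20.0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            popt, _ = optimize.curve_fit(
                f, doses, responses, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError:
            popt = p0
    e_min, e_max, log_ec50, slope = popt
    if e_max < e_min:  # bounded fit can land inverted on flat data
        e_min = e_max = float(np.mean(responses))
    resid = f(doses, e_min, max(e_max, e_min), log_ec50, slope) - responses
    rmse = float(np.sqrt(np.mean(resid**2)))
    return HillParams(
        e_min=float(e_min),
        e_max=float(max(e_max, e_min)),
        ec50=float(10.0**log_ec50),
        slope=float(slope),
        rmse=rmse,
        flagged=rmse > 0.15 or abs(e_max - e_min) < 1e-6,
    )


def _loewe_expected(
    x_a: float, x_b: float, hill_a: HillParams, hill_b: HillParams
) -> tuple[float, bool]:
    """Solve x_a/D_a(y) + x_b/D_b(y) = 1 for y by bracketed root finding.

    Returns (expected response, clamped flag). Degenerate single-drug doses
    reduce to the monotherapy response; a y outside both achievable ranges is
    clamped to min(e_max_a, e_max_b).
    """
    if x_a <= 0 and x_b <= 0:
        return max(hill_a.e_min, hill_b.e_min), False
    if x_a <= 0:
        return float(hill_b(x_b)), False
    if x_b <= 0:
        return float(hill_a(x_a)), False
    lo = max(hill_a.e_min, hill_b.e_min)
    hi = min(hill_a.e_max, hill_b.e_max)
    if hi - lo < 1e-9:
        return hi, True
    eps = 1e-12

    def g(y: float) -> float:
        total = 0.0
        for x, h in ((x_a, hill_a), (x_b, hill_b)):
            yy = min(max(y, h.e_min + eps), h.e_max - eps)
            total += x / h.inverse(yy)
        return total - 1.0

    y_lo = lo + 1e-9 * (hi - lo)
    y_hi = hi - 1e-9 * (hi - lo)
    g_hi = g(y_hi)
    if g_hi > 0:  # doses exceed what the shallower drug can ever reach
        return hi, True
    g_lo = g(y_lo)
    if g_lo < 0:
        return lo, True
    y = optimize.brentq(g, y_lo, y_hi, xtol=1e-10)
    return float(y), False


def expected_response(
    model: str,
    x_a: float,
    x_b: float,
    hill_a: HillParams,
    hill_b: HillParams,
) -> float:
    """Null-model expected combination response at one dose pair.

    HSA and Bliss evaluate the Hill curves directly; Loewe and ZIP both use
    the dose-additivity / independence constructions described in the module
    docstring (ZIP's expectation is the Bliss form on the fitted curves — its
    full delta also smooths the observed surface, see :func:`synergy_score`).
    """
    model = model.lower()
    y_a = float(hill_a(x_a))
    y_b = float(hill_b(x_b))
    if model == "hsa":
        return max(y_a, y_b)
    if model in ("bliss", "zip"):
        return y_a + y_b - y_a * y_b
    if model == "loewe":
        return _loewe_expected(x_a, x_b, hill_a, hill_b)[0]
    raise ValueError(f"unknown synergy model {model!r}")


def _conditional_fit(
    doses: np.ndarray, responses: np.ndarray, baseline: float
) -> np.ndarray:
    """Refit one slice of the combination surface as a Hill curve with a fixed
    lower asymptote (the partner drug's fitted effect); returns the smoothed
    responses at the slice's doses. Falls back to the raw slice on failure."""

    def f(x, e_max, log_ec50, slope):
        return baseline + (e_max - baseline) / (1.0 + (10.0**log_ec50 / x) ** slope)

    lo_d, hi_d = math.log10(doses.min()), math.log10(doses.max())
    p0 = [min(1.0, max(baseline, float(responses.max()))), 0.5 * (lo_d + hi_d), 1.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                f,
                doses,
                np.clip(responses, 0, 1),
                p0=p0,
                bounds=([0.0, lo_d - 3, 0.05], [1.0, hi_d + 3, 20.0]),
                maxfev=10000,
            )
        return f(doses, *popt)
    except (RuntimeError, ValueError):
        return responses


def _zip_delta(
    surface: DoseResponseSurface, hill_a: HillParams, hill_b: HillParams
) -> np.ndarray:
    """ZIP delta: conditionally refitted surface minus the Bliss-form
    expectation on fitted monotherapy curves, averaged over both directions."""
    ya = np.asarray(hill_a(surface.doses_a))
    yb = np.asarray(hill_b(surface.doses_b))
    zip_exp = ya[:, None] + yb[None, :] - ya[:, None] * yb[None, :]
    na, nb = surface.combo.shape
    fit_along_a = np.empty_like(surface.combo)
    for j in range(nb):
        base = hill_a.e_min + yb[j] - hill_a.e_min * yb[j]
        fit_along_a[:, j] = _conditional_fit(
            surface.doses_a, surface.combo[:, j], base
        )
    fit_along_b = np.empty_like(surface.combo)
    for i in range(na):
        base = hill_b.e_min + ya[i] - hill_b.e_min * ya[i]
        fit_along_b[i, :] = _conditional_fit(
            surface.doses_b, surface.combo[i, :], base
        )
    smoothed = 0.5 * (fit_along_a + fit_along_b)
    return smoothed - zip_exp


def synergy_score(surface: DoseResponseSurface, model: str) -> SynergyResult:
    """Score one combination surface under a reference model.

    HSA and Bliss compare against expectations built from the *observed*
    monotherapy responses; Loewe and ZIP require Hill fits of the
    monotherapies. The summary score is 100 × mean excess over all
    combination cells (percent scale; 10 ≈ ten percentage points of
    inhibition beyond the null model).
    """
    model = model.lower()
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    flags: list[str] = []
    if model == "hsa":
        exp = np.maximum(surface.mono_a[:, None], surface.mono_b[None, :])
        excess = surface.combo - exp
    elif model == "bliss":
        ya = surface.mono_a[:, None]
        yb = surface.mono_b[None, :]
        exp = ya + yb - ya * yb
        excess = surface.combo - exp
    else:
        hill_a = fit_hill(surface.doses_a, surface.mono_a)
        hill_b = fit_hill(surface.doses_b, surface.mono_b)
        if hill_a.flagged or hill_b.flagged:
            flags.append("poor monotherapy Hill fit")
        if model == "loewe":
            exp = np.empty_like(surface.combo)
            clamped = 0
            for i, xa in enumerate(surface.doses_a):
                for j, xb in enumerate(surface.doses_b):
                    exp[i, j], cl = _loewe_expected(xa, xb, hill_a, hill_b)
                    clamped += cl
            if clamped:
                flags.append(f"loewe expectation clamped at {clamped} cells")
            excess = surface.combo - exp
        else:  # zip
            excess = _zip_delta(surface, hill_a, hill_b)
            ya = np.asarray(hill_a(surface.doses_a))[:, None]
            yb = np.asarray(hill_b(surface.doses_b))[None, :]
            exp = ya + yb - ya * yb
    return SynergyResult(
        model=model,
        excess=excess,
        score=float(100.0 * excess.mean()),
        expected=exp,
        flags=flags,
    )


def combination_ratio(surface: DoseResponseSurface) -> tuple[np.ndarray, float, int]:
    """CR per dose pair = combo / max(single agents); > 1 means the pair beats
    the better monotherapy. Cells with a zero best single agent are undefined
    (NaN) and excluded from the mean; their count is returned."""
    best = np.maximum(surface.mono_a[:, None], surface.mono_b[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        cr = np.where(best > 0, surface.combo / best, np.nan)
    n_undefined = int(np.isnan(cr).sum())
    defined = cr[~np.isnan(cr)]
    if defined.size == 0:
        raise ValueError("combination ratio undefined everywhere (all-zero singles)")
    return cr, float(defined.mean()), n_undefined


def dss(doses, responses, activity_threshold: float = 0.10) -> float:
    """Normalized-AUC drug sensitivity score in [0, 100].

    Integrates max(response − threshold, 0) over log10 dose by the trapezoid
    rule and normalizes by the maximal attainable area
    (1 − threshold) × log10-dose range. Higher means more sensitive.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.size < 2:
        raise ValueError("need at least 2 dose points for DSS")
    if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be positive and strictly increasing")
    t = activity_threshold
    ex = np.maximum(responses - t, 0.0)
    lg = np.log10(doses)
    area = float(np.trapezoid(ex, lg))
    full = (1.0 - t) * (lg[-1] - lg[0])
    return 100.0 * area / full


def read_combo_csv(path) -> list[DoseResponseSurface]:
    """Read long-format combination data: drug1, drug2, dose1, dose2, response
    (+ optional replicate column, averaged). Rows with dose2 = 0 are drug-1
    monotherapy; dose1 = 0 rows are drug-2 monotherapy."""
    df = pd.read_csv(path)
    df = (
        df.groupby(["drug1", "drug2", "dose1", "dose2"], as_index=False)["response"]
        .mean()
    )
    out = []
    for (d1, d2), grp in df.groupby(["drug1", "drug2"]):
        mono_a = grp[(grp.dose1 > 0) & (grp.dose2 == 0)].sort_values("dose1")
        mono_b = grp[(grp.dose1 == 0) & (grp.dose2 > 0)].sort_values("dose2")
        comb = grp[(grp.dose1 > 0) & (grp.dose2 > 0)]
        da = mono_a["dose1"].to_numpy()
        db = mono_b["dose2"].to_numpy()
        grid = (
            comb.pivot(index="dose1", columns="dose2", values="response")
            .reindex(index=da, columns=db)
            .to_numpy()
        )
        out.append(
            DoseResponseSurface(
                drug_a=str(d1),
                drug_b=str(d2),
                doses_a=da,
                doses_b=db,
                mono_a=mono_a["response"].to_numpy(),
                mono_b=mono_b["response"].to_numpy(),
                combo=grid,
            )
        )
    return out


def write_combo_csv(surfaces: list[DoseResponseSurface], path) -> None:
    rows = []
    for s in surfaces:
        for x, y in zip(s.doses_a, s.mono_a):
            rows.append((s.drug_a, s.drug_b, x, 0.0, y))
        for x, y in zip(s.doses_b, s.mono_b):
            rows.append((s.drug_a, s.drug_b, 0.0, x, y))
        for i, xa in enumerate(s.doses_a):
            for j, xb in enumerate(s.doses_b):
                rows.append((s.drug_a, s.drug_b, xa, xb, s.combo[i, j]))
    pd.DataFrame(
        rows, columns=["drug1", "drug2", "dose1", "dose2", "response"]
    ).to_csv(path, index=False)
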