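"""Bench-assay quantification: qPCR, reporter, imaging and dose-response.

Pure table-in / table-out calculators for the quantitative readouts
surrounding the enhancer analysis:

* 3C interaction frequency  2^(Ct(BAC) − Ct(3C)) against a ligated
  BAC control template,
* ChIP-qPCR percent input,
* dual-luciferase reporter activity (Renilla, then empty-vector
  normalized),
* delta-delta-Ct expression fold change,
* per-nucleus immunofluorescence signal (area x mean intensity) and
  positive-cell fractions with optional Ki67+/CD45− gating,
* four-parameter logistic dose-response fitting with relative IC50,
* per-day proliferation fold change from confluency series.

All Ct arithmetic assumes perfect per-cycle doubling (efficiency 2.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

CT_ROLES = ("test_3C", "control_BAC", "chip", "input", "gene", "reference_gene")


class AssayError(ValueError):
    """Raised for invalid assay inputs."""


class DoseResponseFitError(RuntimeError):
    """Raised when a dose-response curve cannot be fitted."""


@dataclass(frozen=True)
class CtMeasurement:
    """Replicate Ct values for one sample/target."""

    sample: str
    target: str
    ct: tuple[float, ...]
    role: str = "gene"

    def __post_init__(self) -> None:
        if len(self.ct) < 1:
            raise AssayError("need at least one Ct replicate")
        if any(c <= 0 for c in self.ct):
            raise AssayError("Ct values must be positive")
        if self.role not in CT_ROLES:
            raise AssayError(f"unknown role {self.role!r}")

    @property
    def mean(self) -> float:
        return float(np.mean(self.ct))

    @property
    def sem(self) -> float:
        if len(self.ct) < 2:
            return 0.0
        return float(np.std(self.ct, ddof=1) / math.sqrt(len(self.ct)))


def _mean_ct(ct: "CtMeasurement | Sequence[float] | float") -> float:
    if isinstance(ct, CtMeasurement):
        return ct.mean
    if np.isscalar(ct):
        return float(ct)
    return float(np.mean(ct))


def _sem_ct(ct: "CtMeasurement | Sequence[float] | float") -> float:
    if isinstance(ct, CtMeasurement):
        return ct.sem
    if np.isscalar(ct):
        return 0.0
    arr = np.asarray(ct, dtype=float)
    return float(np.std(arr, ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0


# ---------------------------------------------------------------------------
# qPCR-based readouts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionFrequency:
    frequency: float
    replicate_frequencies: tuple[float, ...]
    # standard error of the frequency, with and without propagating the
    # BAC-control replicate variance
    se_with_bac: float
    se_without_bac: float


def interaction_frequency(
    ct_3c: "CtMeasurement | Sequence[float]",
    ct_bac: "CtMeasurement | Sequence[float]",
) -> InteractionFrequency:
    """Relative 3C ligation frequency, BAC-control normalized.

    frequency = 2^(mean Ct(BAC) − mean Ct(3C)).  Equal Cts give 1;
    every extra cycle on the 3C template halves the frequency.
    Replicate-level frequencies use the mean BAC Ct; standard errors
    come from the delta method on the Ct difference.
    """
    if ct_bac is None:
        raise AssayError("BAC control measurement is required")
    mean_3c, mean_bac = _mean_ct(ct_3c), _mean_ct(ct_bac)
    freq = 2.0 ** (mean_bac - mean_3c)
    reps = tuple(
        2.0 ** (mean_bac - float(c))
        for c in (ct_3c.ct if isinstance(ct_3c, CtMeasurement) else np.atleast_1d(ct_3c))
    )
    se_3c, se_bac = _sem_ct(ct_3c), _sem_ct(ct_bac)
    ln2 = math.log(2.0)
    return InteractionFrequency(
        frequency=freq,
        replicate_frequencies=reps,
        se_with_bac=freq * ln2 * math.hypot(se_3c, se_bac),
        se_without_bac=freq * ln2 * se_3c,
    )


def percent_input(
    ct_chip: "CtMeasurement | Sequence[float]",
    ct_input: "CtMeasurement | Sequence[float]",
    input_fraction: float = 0.01,
) -> float:
    """ChIP enrichment as percent of input chromatin.

    The measured input is only ``input_fraction`` of the chromatin, so
    its Ct is first adjusted by −log2(1/input_fraction) to represent
    100% input; then %input = 100 · 2^(adjusted Ct(input) − Ct(chip)).
    Equivalently 100 · input_fraction · 2^(Ct(input) − Ct(chip)).
    """
    if not (0 < input_fraction <= 1):
        raise AssayError("input_fraction must be in (0, 1]")
    return 100.0 * input_fraction * 2.0 ** (_mean_ct(ct_input) - _mean_ct(ct_chip))


def dual_luciferase(
    firefly_test: float,
    renilla_test: float,
    firefly_vector: float,
    renilla_vector: float,
) -> float:
    """Reporter activity, transfection- and vector-normalized.

    Firefly is divided by Renilla (internal transfection control) and
    the test ratio by the empty-vector ratio, so the result is
    invariant to instrument scale.
    """
    for name, value in (
        ("firefly_test", firefly_test),
        ("renilla_test", renilla_test),
        ("firefly_vector", firefly_vector),
        ("renilla_vector", renilla_vector),
    ):
        if value <= 0:
            raise AssayError(f"{name} must be positive (failed transfection?)")
    return (firefly_test / renilla_test) / (firefly_vector / renilla_vector)


def ddct_fold_change(
    ct_gene: "CtMeasurement | Sequence[float] | float",
    ct_reference: "CtMeasurement | Sequence[float] | float",
    ct_gene_control: "CtMeasurement | Sequence[float] | float",
    ct_reference_control: "CtMeasurement | Sequence[float] | float",
) -> float:
    """Delta-delta-Ct relative expression.

    2^−ΔΔCt with ΔΔCt = (Ct_gene − Ct_ref)_sample − (Ct_gene − Ct_ref)_control:
    the target is normalized to a reference gene (e.g. actin) and
    expressed relative to a control sample.
    """
    d_sample = _mean_ct(ct_gene) - _mean_ct(ct_reference)
    d_control = _mean_ct(ct_gene_control) - _mean_ct(ct_reference_control)
    return 2.0 ** (-(d_sample - d_control))


# ---------------------------------------------------------------------------
# immunofluorescence
# ---------------------------------------------------------------------------

def nuclear_signal(area: float, mean_intensity: float) -> float:
    """Total per-nucleus signal = nuclear area x average intensity."""
    if area <= 0:
        raise AssayError("nucleus area must be positive")
    if mean_intensity < 0:
        raise AssayError("mean intensity must be non-negative")
    return area * mean_intensity


def signal_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Add a ``signal`` column (area x mean_intensity) to a long-format
    per-nucleus table with columns nucleus_id, channel, area, mean_intensity."""
    required = {"nucleus_id", "channel", "area", "mean_intensity"}
    missing = required - set(measurements.columns)
    if missing:
        raise AssayError(f"measurement table lacks columns {sorted(missing)}")
    if (measurements["area"] <= 0).any():
        raise AssayError("nucleus area must be positive")
    out = measurements.copy()
    out["signal"] = out["area"] * out["mean_intensity"]
    return out


def threshold_from_negative(negative_signals: Sequence[float], k: float = 3.0) -> float:
    """Positivity threshold as k x median of a negative-control signal set."""
    arr = np.asarray(negative_signals, dtype=float)
    if arr.size == 0:
        raise AssayError("negative-control set is empty")
    return float(k * np.median(arr))


def positive_fraction(
    measurements: pd.DataFrame, channel: str, threshold: float
) -> float:
    """Fraction of nuclei whose ``channel`` signal exceeds ``threshold``."""
    table = signal_table(measurements)
    sub = table[table["channel"] == channel]
    if sub.empty:
        raise AssayError(f"no measurements for channel {channel!r}")
    return float((sub["signal"] > threshold).mean())


def gated_positive_fraction(
    measurements: pd.DataFrame,
    target_channel: str,
    thresholds: dict[str, float],
    require_positive: Sequence[str] = ("Ki67",),
    require_negative: Sequence[str] = ("CD45",),
) -> float:
    """Fraction of gated cells positive for ``target_channel``.

    The gate keeps nuclei positive for every channel in
    ``require_positive`` and negative for every channel in
    ``require_negative`` (e.g. Ki67+/CD45− proliferating tumor cells),
    then reports the target-positive fraction within the gate.
    """
    table = signal_table(measurements)
    wide = table.pivot(index="nucleus_id", columns="channel", values="signal")
    needed = set(require_positive) | set(require_negative) | {target_channel}
    missing = needed - set(wide.columns)
    if missing:
        raise AssayError(f"unknown channel(s) {sorted(missing)}")
    mask = pd.Series(True, index=wide.index)
    for ch in require_positive:
        mask &= wide[ch] > thresholds[ch]
    for ch in require_negative:
        mask &= wide[ch] <= thresholds[ch]
    gated = wide.loc[mask]
    if gated.empty:
        raise AssayError("gate selected no cells")
    return float((gated[target_channel] > thresholds[target_channel]).mean())


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    doses: np.ndarray
    responses: np.ndarray
    bottom: float
    top: float
    hill: float
    ic50: float
    residuals: np.ndarray = field(repr=False, default=None)

    @property
    def log2_ic50(self) -> float:
        return math.log2(self.ic50)


def four_param_logistic(
    dose: np.ndarray, bottom: float, top: float, hill: float, log_ic50: float
) -> np.ndarray:
    """4PL: bottom + (top − bottom) / (1 + (dose/IC50)^hill).

    Response falls from ``top`` toward ``bottom`` with increasing dose
    for hill > 0; dose 0 maps exactly to ``top``.
    """
    dose = np.asarray(dose, dtype=float)
    ic50 = math.exp(log_ic50)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_dose_response(
    doses: Sequence[float], responses: Sequence[float]
) -> DoseResponseFit:
    """Least-squares four-parameter logistic fit; IC50 is the relative
    (inflection-point) IC50.

    Requires at least 4 distinct doses.  A flat response or a
    non-converging optimizer raises :class:`DoseResponseFitError`
    rather than returning a silent value.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise AssayError("doses and responses must have equal length")
    if (doses < 0).any():
        raise AssayError("doses must be non-negative")
    if len(np.unique(doses)) < 4:
        raise AssayError("need at least 4 distinct doses")
    spread = responses.max() - responses.min()
    if spread <= 1e-9 * max(1.0, abs(responses.max())):
        raise DoseResponseFitError("response is flat; IC50 is unidentifiable")

    positive = doses[doses > 0]
    mid = 0.5 * (responses.max() + responses.min())
    # initial IC50: positive dose whose mean response is closest to midway
    by_dose = pd.Series(responses[doses > 0]).groupby(positive).mean()
    ic50_init = float(by_dose.index[np.argmin(np.abs(by_dose.to_numpy() - mid))])
    p0 = [float(responses.min()), float(responses.max()), 1.0, math.log(ic50_init)]
    try:
        params, _ = optimize.curve_fit(
            four_param_logistic, doses, responses, p0=p0, maxfev=20_000
        )
    except (RuntimeError, ValueError) as exc:
        raise DoseResponseFitError(f"4PL fit failed: {exc}") from exc
    bottom, top, hill, log_ic50 = params
    fitted = four_param_logistic(doses, *params)
    residuals = responses - fitted
    if not np.all(np.isfinite(residuals)):
        raise DoseResponseFitError("4PL fit produced non-finite residuals")
    return DoseResponseFit(
        doses=doses,
        responses=responses,
        bottom=float(bottom),
        top=float(top),
        hill=float(hill),
        ic50=float(math.exp(log_ic50)),
        residuals=residuals,
    )


def ic50(fit: DoseResponseFit) -> float:
    return fit.ic50


# ---------------------------------------------------------------------------
# proliferation
# ---------------------------------------------------------------------------

def proliferation_rate(days: Sequence[float], confluency: Sequence[float]) -> pd.Series:
    """Per-day fold change in confluency relative to Day 0."""
    days = np.asarray(days, dtype=float)
    confluency = np.asarray(confluency, dtype=float)
    if days.shape != confluency.shape or len(days) == 0:
        raise AssayError("days and confluency must be equal-length, non-empty")
    order = np.argsort(days)
    days, confluency = days[order], confluency[order]
    if days[0] != 0:
        raise AssayError("series must start at Day 0")
    if confluency[0] <= 0:
        raise AssayError("Day 0 confluency must be positive")
    return pd.Series(confluency / confluency[0], index=days, name="fold_change")


def growth_rate(days: Sequence[float], confluency: Sequence[float]) -> float:
    """Exponential growth rate (doublings/day) from a log-linear fit."""
    days = np.asarray(days, dtype=float)
    confluency = np.asarray(confluency, dtype=float)
    if (confluency <= 0).any():
        raise AssayError("confluency must be positive for a log-linear fit")
    slope, *_ = stats.linregress(days, np.log2(confluency))
    return float(slope)
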