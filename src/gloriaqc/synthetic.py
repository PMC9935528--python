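"""Synthetic hyperspectral reflectance generator with labeled artifacts.

Generates GLORIA-layout R_rs tables (1 nm, 350-900 nm) whose spectra are
smooth, strictly positive sums of broad Gaussian components decaying toward
the NIR — shapes spanning clear to turbid/eutrophic waters — plus
injectable artifacts with known ground-truth flag outcomes:

* band-limited high-frequency noise in the red (750-900 nm) or blue
  (350-400 nm) QC windows,
* additive baseline offsets (positive: glint residual pushing the whole
  spectrum up; negative: overcorrection driving the NIR negative),
* a narrow oxygen A-band absorption artifact near 762 nm,
* a negative UV-blue tilt.

Artifact amplitudes must be sized decisively relative to the QC thresholds
(outside a +/-50% exclusion band) so the expected flag outcome is provable;
near-threshold requests are rejected.  Every generated spectrum is verified
against the flag suite at generation time — the ground-truth labels are
construction-defined and the generator resamples the base shape if a side
effect would contradict them.

A strong positive baseline offset flattens the spectral shape, which drives
the QWIP score toward -P(AVW_flat) ~ +0.36; the ground truth for that
artifact therefore expects QWIP_fail = 1 in addition to Baseline_shift = 1.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import qc
from .io import SampleRecord, SpectralTable, WATER_TYPES
from .metrics import qwip_score
from .spectra import DEFAULT_GRID, Quantity, Spectrum, fit_window, standardize

ArtifactKind = Literal[
    "none", "red_noise", "blue_noise", "baseline_offset", "oxygen_feature", "uv_tilt"
]

PROCEDURAL_FLAGS = qc.PROCEDURAL_FIELDS  # the six computable flags


class ArtifactSizingError(ValueError):
    """Artifact amplitude falls in the ambiguous band around a QC threshold."""


class CleanGenerationError(RuntimeError):
    """Could not produce a spectrum consistent with its ground truth."""


class ArtifactSpec(BaseModel):
    """One artifact to inject, with decisive sizing.

    amplitude semantics by kind:
      red_noise / blue_noise   random-sign noise amplitude in standardized
                               units (approximately the resulting RMSE)
      oxygen_feature           bump height in standardized units
      uv_tilt                  target fitted slope of the standardized
                               spectrum over 350-420 nm, per nm (negative)
      baseline_offset sign=+1  target min/median ratio after the shift
      baseline_offset sign=-1  offset as a multiple of the 765-900 nm
                               maximum, subtracted everywhere
    """

    kind: ArtifactKind = "none"
    amplitude: float = 0.0
    sign: int = 1  # baseline_offset only
    width_nm: float = 1.5  # oxygen_feature only

    @model_validator(mode="after")
    def _decisive(self) -> "ArtifactSpec":
        a = self.amplitude
        band: Optional[tuple[float, float]] = None
        if self.kind == "red_noise":
            band = (0.5 * qc.NOISY_RED_RMSE, 1.5 * qc.NOISY_RED_RMSE)
        elif self.kind == "blue_noise":
            band = (0.5 * qc.NOISY_BLUE_RMSE, 1.5 * qc.NOISY_BLUE_RMSE)
        elif self.kind == "oxygen_feature":
            band = (0.5 * qc.OXYGEN_HEIGHT, 1.5 * qc.OXYGEN_HEIGHT)
        elif self.kind == "uv_tilt":
            if a >= 0:
                raise ArtifactSizingError("uv_tilt amplitude must be negative")
            a = abs(a)
            band = (0.5 * abs(qc.UV_SLOPE), 1.5 * abs(qc.UV_SLOPE))
        elif self.kind == "baseline_offset":
            if self.sign not in (1, -1):
                raise ValueError("baseline_offset sign must be +1 or -1")
            if self.sign > 0:
                # ratio threshold 0.6 is bounded above by 1, so a +/-50%
                # band is infeasible; +/-25% keeps outcomes decisive.
                band = (0.75 * qc.UPSHIFT_MIN_TO_MEDIAN, 1.25 * qc.UPSHIFT_MIN_TO_MEDIAN)
            else:
                if a < 1.5:
                    raise ArtifactSizingError(
                        "negative baseline_offset supports only decisive "
                        "flag-1 sizing: amplitude >= 1.5 x the NIR maximum"
                    )
                band = None
        if band is not None and band[0] + 1e-9 < a < band[1] - 1e-9:
            raise ArtifactSizingError(
                f"{self.kind} amplitude {self.amplitude} lies in the ambiguous "
                f"band ({band[0]:g}, {band[1]:g}) around the QC threshold; "
                "size it decisively (<= lower or >= upper bound)"
            )
        return self

    def expected_flags(self) -> dict[str, int]:
        """Ground-truth procedural flags implied by this artifact's sizing."""
        exp = {name: 0 for name in PROCEDURAL_FLAGS}
        a = abs(self.amplitude)
        if self.kind == "red_noise" and a > qc.NOISY_RED_RMSE:
            exp["noisy_red"] = 1
        elif self.kind == "blue_noise" and a > qc.NOISY_BLUE_RMSE:
            exp["noisy_blue"] = 1
        elif self.kind == "oxygen_feature" and a > qc.OXYGEN_HEIGHT:
            exp["oxygen_signal"] = 1
        elif self.kind == "uv_tilt" and self.amplitude < qc.UV_SLOPE:
            exp["negative_uv_slope"] = 1
        elif self.kind == "baseline_offset":
            if self.sign > 0 and a > qc.UPSHIFT_MIN_TO_MEDIAN:
                exp["baseline_shift"] = 1
                exp["qwip_fail"] = 1  # flattened shape leaves the QWIP envelope
            elif self.sign < 0:
                exp["baseline_shift"] = 1
        return exp


class BaseShapeParams(BaseModel):
    """Ranges for the smooth base reflectance shapes (uniform draws)."""

    peak_wavelength: tuple[float, float] = (450.0, 620.0)  # nm
    peak_magnitude: tuple[float, float] = (0.002, 0.03)  # sr^-1
    peak_width: tuple[float, float] = (70.0, 100.0)  # nm
    secondary_amplitude: tuple[float, float] = (0.0, 0.2)  # relative
    secondary_wavelength: tuple[float, float] = (540.0, 700.0)  # nm
    secondary_width: tuple[float, float] = (30.0, 60.0)  # nm


class SyntheticConfig(BaseModel):
    """Study conditions for a synthetic dataset."""

    n_samples: int = Field(default=100, ge=0)
    seed: int = 20230216
    wavelength_range: tuple[int, int] = (350, 900)
    base_shape: BaseShapeParams = Field(default_factory=BaseShapeParams)
    artifact_plan: Optional[list[ArtifactSpec]] = None  # default: mixed cycle
    plant_wq_outliers: bool = True
    max_attempts: int = 60

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


#: default mixed artifact cycle: ~half clean, every artifact kind exercised
#: at both decisive sizes where a flag-0 size is well defined.
DEFAULT_ARTIFACT_CYCLE: list[ArtifactSpec] = [
    ArtifactSpec(kind="none"),
    ArtifactSpec(kind="red_noise", amplitude=0.30),
    ArtifactSpec(kind="none"),
    ArtifactSpec(kind="blue_noise", amplitude=0.25),
    ArtifactSpec(kind="red_noise", amplitude=0.08),
    ArtifactSpec(kind="oxygen_feature", amplitude=0.20),
    ArtifactSpec(kind="none"),
    ArtifactSpec(kind="oxygen_feature", amplitude=0.04),
    ArtifactSpec(kind="uv_tilt", amplitude=-0.0075),
    ArtifactSpec(kind="none"),
    ArtifactSpec(kind="uv_tilt", amplitude=-0.002),
    ArtifactSpec(kind="baseline_offset", amplitude=0.80, sign=1),
    ArtifactSpec(kind="blue_noise", amplitude=0.06),
    ArtifactSpec(kind="baseline_offset", amplitude=2.0, sign=-1),
    ArtifactSpec(kind="none"),
    ArtifactSpec(kind="none"),
]


class GroundTruth(BaseModel, arbitrary_types_allowed=True):
    """Expected QC outcomes for a generated dataset.

    ``flags``: one row per sample, columns gloria_id + the six procedural
    flags (0/1).  ``wq_outliers``: the planted water-quality outliers
    (gloria_id, variable).
    """

    flags: pd.DataFrame
    wq_outliers: pd.DataFrame


# ---------------------------------------------------------------------------
# base spectra
# ---------------------------------------------------------------------------


def _base_values(
    grid: np.ndarray,
    peak_nm: float,
    magnitude: float,
    width: float,
    sec_amp: float,
    sec_nm: float,
    sec_width: float,
) -> np.ndarray:
    lam = grid
    # broad pigment/sediment peak + optional secondary feature + flat floor,
    # all damped by a smooth NIR falloff (pure water absorption dominates)
    shape = (
        0.02
        + np.exp(-((lam - peak_nm) ** 2) / (2 * width**2))
        + sec_amp * np.exp(-((lam - sec_nm) ** 2) / (2 * sec_width**2))
    )
    falloff = 0.015 + 0.985 / (1.0 + np.exp((lam - 720.0) / 30.0))
    return magnitude * shape * falloff


def _is_decisively_clean(s: Spectrum) -> bool:
    """True when every procedural flag is 0 with margin to spare.

    Margins (half the QC thresholds, and |QWIP| <= 0.12) keep the clean
    false-positive rate at zero by construction and leave artifacts room to
    act without ambiguity.
    """
    flags = {
        "noisy_red": qc.flag_noisy_red(s),
        "noisy_blue": qc.flag_noisy_blue(s),
        "baseline_shift": qc.flag_baseline_shift(s),
        "oxygen_signal": qc.flag_oxygen(s),
        "negative_uv_slope": qc.flag_negative_uv_slope(s),
        "qwip_fail": qc.flag_qwip(s),
    }
    if any(v != 0 for v in flags.values()):
        return False
    v = s.finite_values()
    if np.min(v) <= 0:
        return False
    if np.min(v) / np.median(v) > 0.45:
        return False
    from . import metrics as _m

    if _m.oxygen_peak_height(s) > 0.05:
        return False
    if abs(qwip_score(s)) > 0.12:
        return False
    z = standardize(s)
    if fit_window(z, qc.NOISY_RED_WINDOW, 4).rmse > 0.1:
        return False
    if fit_window(z, qc.NOISY_BLUE_WINDOW, 4).rmse > 0.075:
        return False
    if fit_window(z, qc.UV_SLOPE_WINDOW, 1).slope < -0.0025:
        return False
    return True


def generate_base_spectrum(
    params: BaseShapeParams,
    rng: np.random.Generator,
    grid: np.ndarray | None = None,
    max_attempts: int = 60,
) -> Spectrum:
    """Draw a smooth, strictly positive R_rs spectrum that raises no flag.

    The candidate is checked against the full procedural flag suite (with
    margins) and redrawn on failure; a bounded number of attempts guards
    against degenerate parameter ranges.
    """
    grid = DEFAULT_GRID.astype(float) if grid is None else np.asarray(grid, float)
    for _ in range(max_attempts):
        values = _base_values(
            grid,
            peak_nm=rng.uniform(*params.peak_wavelength),
            magnitude=rng.uniform(*params.peak_magnitude),
            width=rng.uniform(*params.peak_width),
            sec_amp=rng.uniform(*params.secondary_amplitude),
            sec_nm=rng.uniform(*params.secondary_wavelength),
            sec_width=rng.uniform(*params.secondary_width),
        )
        s = Spectrum(grid, values, Quantity.RRS)
        if _is_decisively_clean(s):
            return s
    raise CleanGenerationError(
        f"no clean base spectrum within {max_attempts} attempts; "
        "base-shape parameter ranges are likely degenerate"
    )


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------


def _apply_artifact(
    s: Spectrum, spec: ArtifactSpec, rng: np.random.Generator
) -> Spectrum:
    out = s.copy()
    lam = out.grid
    v = out.values
    sd = float(np.std(s.finite_values(), ddof=1))
    if spec.kind == "none":
        return out
    if spec.kind in ("red_noise", "blue_noise"):
        if spec.kind == "red_noise":
            # band-limited: start past the oxygen baseline anchor (785 nm)
            # so red noise and the oxygen A-band artifact stay orthogonal
            lo, hi = 786.0, qc.NOISY_RED_WINDOW[1]
        else:
            lo, hi = qc.NOISY_BLUE_WINDOW
        mask = (lam >= lo) & (lam <= hi)
        signs = rng.choice([-1.0, 1.0], size=int(mask.sum()))
        v[mask] += spec.amplitude * sd * signs
    elif spec.kind == "oxygen_feature":
        bump = np.exp(-((lam - 762.0) ** 2) / (2 * spec.width_nm**2))
        v += spec.amplitude * sd * bump
    elif spec.kind == "uv_tilt":
        z = standardize(s)
        s0 = fit_window(z, qc.UV_SLOPE_WINDOW, 1).slope
        ramp_slope = (spec.amplitude - s0) * sd  # raw units per nm
        mask = lam <= qc.UV_SLOPE_WINDOW[1]
        v[mask] += ramp_slope * (lam[mask] - qc.UV_SLOPE_WINDOW[1])
    elif spec.kind == "baseline_offset":
        fin = s.finite_values()
        if spec.sign > 0:
            r = spec.amplitude
            med, mn = float(np.median(fin)), float(np.min(fin))
            delta = max(0.0, (r * med - mn) / (1.0 - r))
            v += delta
        else:
            nir = v[(lam >= qc.DOWNSHIFT_NIR_WINDOW[0]) & (lam <= qc.DOWNSHIFT_NIR_WINDOW[1])]
            v -= spec.amplitude * float(np.max(nir))
    return out


def inject_artifact(
    s: Spectrum, spec: ArtifactSpec, rng: np.random.Generator
) -> tuple[Spectrum, dict[str, int]]:
    """Inject one artifact and return (spectrum, expected procedural flags).

    The expected flags are defined by the artifact's decisive sizing; the
    realized flag suite is verified against them and a mismatch (e.g. a side
    effect of the base shape) raises, letting the caller resample the base.
    """
    expected = spec.expected_flags()
    out = _apply_artifact(s, spec, rng)
    realized = {
        "noisy_red": qc.flag_noisy_red(out),
        "noisy_blue": qc.flag_noisy_blue(out),
        "baseline_shift": qc.flag_baseline_shift(out),
        "oxygen_signal": qc.flag_oxygen(out),
        "negative_uv_slope": qc.flag_negative_uv_slope(out),
        "qwip_fail": qc.flag_qwip(out),
    }
    if realized != expected:
        raise CleanGenerationError(
            f"artifact {spec.kind} produced flags {realized}, expected {expected}"
        )
    return out, expected


# ---------------------------------------------------------------------------
# water quality
# ---------------------------------------------------------------------------

# log10-scale (mean, sd) per water type: chla mg m^-3, tss g m^-3,
# acdom440 m^-1, secchi m.  Centers chosen to mimic the log-normal spread of
# optically distinct inland/coastal water classes.
_WQ_LOGNORMAL = {
    "TSS-dominated": dict(chla=(0.7, 0.35), tss=(1.5, 0.40), acdom440=(0.0, 0.30), secchi=(-0.40, 0.25)),
    "Chla-dominated": dict(chla=(1.4, 0.40), tss=(0.9, 0.30), acdom440=(0.0, 0.30), secchi=(-0.10, 0.25)),
    "CDOM-dominated": dict(chla=(0.5, 0.35), tss=(0.4, 0.30), acdom440=(0.7, 0.35), secchi=(0.00, 0.25)),
    "Chla+CDOM-dominated": dict(chla=(1.2, 0.40), tss=(0.7, 0.30), acdom440=(0.5, 0.30), secchi=(-0.15, 0.25)),
    "Moderately turbid coastal": dict(chla=(0.3, 0.30), tss=(0.8, 0.30), acdom440=(-0.3, 0.30), secchi=(0.40, 0.25)),
    "Clear": dict(chla=(-0.3, 0.30), tss=(-0.3, 0.30), acdom440=(-0.7, 0.30), secchi=(0.85, 0.20)),
}

_WATER_BODY_TYPES = ("lake", "estuary", "coastal ocean", "river", "other")

#: minimum group size for planting a 4-sigma outlier: the plant inflates the
#: group SD, and n >= 30 keeps the post-plant z-score above 3.15.
MIN_PLANT_GROUP = 30


def _plant_outliers(
    records: list[SampleRecord], rng: np.random.Generator
) -> pd.DataFrame:
    """Plant one 4-sigma outlier per (water type, variable) group of >= 30.

    The plant is set to mean + 4*SD of the *other* group members on the
    log10 scale, which makes its post-plant z-score a deterministic function
    of group size (>= 3.15 for n >= 30), guaranteeing recovery at k = 3.
    """
    planted = []
    by_type: dict[str, list[SampleRecord]] = {}
    for r in records:
        by_type.setdefault(r.water_type, []).append(r)
    from .screening import WQ_VARIABLES

    for wt in sorted(by_type):
        members = by_type[wt]
        if len(members) < MIN_PLANT_GROUP:
            continue
        for var in WQ_VARIABLES:
            target = members[int(rng.integers(len(members)))]
            others = [
                np.log10(getattr(r, var))
                for r in members
                if r is not target and getattr(r, var) is not None
            ]
            if len(others) < MIN_PLANT_GROUP - 1:
                continue
            mu, sd = float(np.mean(others)), float(np.std(others, ddof=1))
            setattr(target, var, float(10 ** (mu + 4.0 * sd)))
            planted.append({"gloria_id": target.gloria_id, "variable": var})
    return pd.DataFrame(planted, columns=["gloria_id", "variable"])


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def generate_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[SpectralTable, list[SampleRecord], GroundTruth]:
    """Generate a full synthetic dataset: spectra, metadata, ground truth.

    Deterministic for a fixed config (single seeded generator).  Each sample
    gets an artifact from the configured plan (default: a mixed cycle with
    roughly half clean spectra), and the expected flag matrix plus planted
    water-quality outliers are returned as ground truth.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.wavelength_range
    grid = np.arange(lo, hi + 1, dtype=float)
    plan = config.artifact_plan
    n = config.n_samples

    ids, rows, truth_rows = [], [], []
    records: list[SampleRecord] = []
    for i in range(n):
        gid = f"GLORIA_SYN_{i + 1:04d}"
        spec = (
            plan[i % len(plan)]
            if plan
            else DEFAULT_ARTIFACT_CYCLE[i % len(DEFAULT_ARTIFACT_CYCLE)]
        )
        for _ in range(config.max_attempts):
            base = generate_base_spectrum(
                config.base_shape, rng, grid, config.max_attempts
            )
            try:
                s, expected = inject_artifact(base, spec, rng)
                break
            except CleanGenerationError:
                continue
        else:
            raise CleanGenerationError(
                f"sample {gid}: artifact {spec.kind} incompatible with any "
                f"base shape in {config.max_attempts} attempts"
            )
        ids.append(gid)
        rows.append(s.values)
        truth_rows.append({"gloria_id": gid, **expected})

        wt = WATER_TYPES[i % len(WATER_TYPES)]
        dists = _WQ_LOGNORMAL[wt]
        wq = {
            var: float(10 ** rng.normal(mu, sd)) for var, (mu, sd) in dists.items()
        }
        records.append(
            SampleRecord(
                gloria_id=gid,
                water_type=wt,
                water_body_type=_WATER_BODY_TYPES[i % len(_WATER_BODY_TYPES)],
                latitude=float(np.round(rng.uniform(-54, 67), 4)),
                longitude=float(np.round(rng.uniform(-122, 178), 4)),
                **wq,
            )
        )

    table = SpectralTable(
        quantity=Quantity.RRS,
        ids=ids,
        grid=grid.astype(int),
        values=np.asarray(rows) if rows else np.empty((0, grid.size)),
    )
    if config.plant_wq_outliers:
        planted = _plant_outliers(records, rng)
    else:
        planted = pd.DataFrame(columns=["gloria_id", "variable"])
    truth = GroundTruth(
        flags=pd.DataFrame(truth_rows, columns=["gloria_id", *PROCEDURAL_FLAGS]),
        wq_outliers=planted,
    )
    return table, records, truth
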