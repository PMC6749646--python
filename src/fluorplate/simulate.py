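"""Synthetic plate imager and chamber: ground-truthed test data generator.

Emulates a pulse-amplitude-modulated imaging session on a plate of excised
leaf sections.  Each genotype is a small parameter set: dark-adapted
Fo/Fm (hence Fv/Fm), a saturating hyperbola for steady-state NPQ versus
PPFD, a reciprocal decline for steady-state qP, and first-order rate
constants for NPQ induction and relaxation.  Under any light protocol the
forward model produces, per saturating pulse, the true NPQ, Fm', Fo' and
F' for every section, renders them into image frames (with optional
multiplicative pixel noise and a background noise floor), and returns the
full ground truth so downstream analysis can be validated exactly.

The chamber side generates gas sensor logs as first-order exponential
approaches to switched supply targets plus sensor noise.

Forward model per pulse at time t with actinic PPFD E:

* NPQ(t): piecewise exponential toward the steady-state target of the
  current phase (induction rate when rising, relaxation rate when
  falling), continuous across phase boundaries, NPQ = 0 at dark start.
* Fm' = Fm / (1 + NPQ)              (inversion of NPQ = (Fm - Fm')/Fm')
* Fo' = Fo / (Fv/Fm + Fo/Fm')       (Oxborough–Baker, shared with analysis)
* F'  = Fm' - qP_ss(E) · (Fm' - Fo')  (inversion of the qP definition)
* dark pulse: F = Fo, Fm' = Fm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cfparams import estimate_fo_prime, fqp_fmp, fvp_fmp, qp as qp_coef
from .gasqc import GAS_LOG_COLUMNS, GasLog
from .imaging import (
    FRAMES_FILENAME,
    PULSE_METADATA_COLUMNS,
    PULSES_FILENAME,
    FrameStack,
)
from .protocol import LightProtocol, pulse_schedule

__all__ = [
    "GenotypeParams",
    "PlateLayout",
    "GroundTruth",
    "GENOTYPE_PRESETS",
    "grid_layout",
    "steady_state_targets",
    "simulate_npq_trajectory",
    "npq_at_times",
    "render_plate",
    "simulate_gas_log",
    "write_dataset",
]

GROUND_TRUTH_FILENAME = "ground_truth.csv"


@dataclass(frozen=True)
class GenotypeParams:
    """Ground-truth physiology of one genotype.

    Attributes
    ----------
    fo_dark, fm_dark : float
        Dark-adapted minimal/maximal fluorescence, counts.
    npq_max : float
        Asymptotic steady-state NPQ at saturating PPFD.
    k_npq : float
        PPFD half-saturation of the steady-state NPQ hyperbola.
    k_qp : float
        PPFD scale of the steady-state qP decline, qP = 1/(1 + E/k_qp).
    b_induction, b_relaxation : float
        First-order rates (s⁻¹) toward a higher / lower NPQ target.
    noise_cv : float
        Coefficient of variation of multiplicative per-pixel noise.
    absorptance : float
        Fraction of incident PPFD absorbed by the leaf.
    """

    fo_dark: float = 190.0
    fm_dark: float = 1000.0
    npq_max: float = 2.5
    k_npq: float = 500.0
    k_qp: float = 500.0
    b_induction: float = 0.1
    b_relaxation: float = 0.008
    noise_cv: float = 0.0
    absorptance: float = 0.84
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.fm_dark > self.fo_dark > 0):
            raise ValueError("requires fm_dark > fo_dark > 0")
        for attr in ("npq_max", "k_npq", "k_qp", "b_induction", "b_relaxation"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.b_induction == 0 or self.b_relaxation == 0:
            raise ValueError("rate constants must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not (0 < self.absorptance <= 1):
            raise ValueError("absorptance must lie in (0, 1]")

    @property
    def fv_fm_true(self) -> float:
        return (self.fm_dark - self.fo_dark) / self.fm_dark


def _preset(name, fo, fm, npq_max, k_npq, half_rise_s, half_relax_s, **kw):
    ln2 = np.log(2.0)
    return GenotypeParams(
        fo_dark=fo, fm_dark=fm, npq_max=npq_max, k_npq=k_npq,
        b_induction=ln2 / half_rise_s, b_relaxation=ln2 / half_relax_s,
        name=name, **kw,
    )


#: Genotype presets for three wheat cultivars with contrasting NPQ
#: behaviour: a high-NPQ/slow-relaxing modern cultivar, a fast-relaxing
#: low-NPQ one, and an intermediate landrace.  All share Fv/Fm = 0.81.
GENOTYPE_PRESETS: dict[str, GenotypeParams] = {
    "paragon": _preset("paragon", 190.0, 1000.0, 4.89, 1222.0, 5.0, 124.5),
    "cs94": _preset("cs94", 190.0, 1000.0, 2.07, 382.0, 4.1, 108.6),
    "pavon76": _preset("pavon76", 190.0, 1000.0, 2.01, 671.0, 9.0, 67.9),
}


@dataclass(frozen=True)
class PlateLayout:
    """Rectangular leaf-section footprints on the camera frame.

    ``sections`` maps sample_id -> (row, col, height, width) in pixels.
    Footprints must be disjoint and inside the frame.
    """

    shape: tuple[int, int]
    sections: dict[int, tuple[int, int, int, int]]
    genotypes: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sections:
            raise ValueError("layout needs at least one section")
        h, w = self.shape
        cover = np.zeros(self.shape, dtype=bool)
        for sid, (r, c, sh, sw) in self.sections.items():
            if sh <= 0 or sw <= 0:
                raise ValueError(f"section {sid}: non-positive footprint")
            if r < 0 or c < 0 or r + sh > h or c + sw > w:
                raise ValueError(f"section {sid}: footprint outside frame")
            block = cover[r:r + sh, c:c + sw]
            if block.any():
                raise ValueError(f"section {sid}: footprint overlaps another")
            cover[r:r + sh, c:c + sw] = True
        unknown = set(self.genotypes) - set(self.sections)
        if unknown:
            raise ValueError(f"genotype assignment for unknown samples {unknown}")

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    def label_map(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=np.int32)
        for sid, (r, c, sh, sw) in self.sections.items():
            out[r:r + sh, c:c + sw] = sid
        return out


def grid_layout(
    n_rows: int = 5,
    n_cols: int = 5,
    shape: tuple[int, int] = (400, 400),
    fill: float = 0.6,
    genotype_cycle: tuple[str, ...] = (),
    jitter_px: int = 0,
    seed: int | None = None,
) -> PlateLayout:
    """Regular grid of rectangular sections, sample IDs in reading order.

    ``fill`` is the fraction of each grid cell the footprint occupies;
    ``jitter_px`` shifts each footprint uniformly at random by up to that
    many pixels (clipped to the cell) to emulate imperfect placement.
    """
    if not (0 < fill < 1):
        raise ValueError("fill must lie in (0, 1)")
    h, w = shape
    cell_h, cell_w = h // n_rows, w // n_cols
    sec_h = max(1, int(cell_h * fill))
    sec_w = max(1, int(cell_w * fill))
    max_jitter = min(jitter_px, (cell_h - sec_h) // 2, (cell_w - sec_w) // 2)
    rng = np.random.default_rng(seed)
    sections, genotypes = {}, {}
    sid = 1
    for i in range(n_rows):
        for j in range(n_cols):
            r = i * cell_h + (cell_h - sec_h) // 2
            c = j * cell_w + (cell_w - sec_w) // 2
            if max_jitter > 0:
                r += int(rng.integers(-max_jitter, max_jitter + 1))
                c += int(rng.integers(-max_jitter, max_jitter + 1))
            sections[sid] = (r, c, sec_h, sec_w)
            if genotype_cycle:
                genotypes[sid] = genotype_cycle[(sid - 1) % len(genotype_cycle)]
            sid += 1
    return PlateLayout(shape=shape, sections=sections, genotypes=genotypes)


def steady_state_targets(params: GenotypeParams, ppfd: float) -> tuple[float, float]:
    """Steady-state (NPQ, qP) targets at a given actinic PPFD.

    NPQ follows a saturating hyperbola npq_max·E/(E + k_npq); qP declines
    as 1/(1 + E/k_qp).  Both are monotone, equal (0, 1) in darkness and
    approach (npq_max, 0) at saturating light.
    """
    if ppfd < 0:
        raise ValueError("ppfd must be >= 0")
    npq_ss = params.npq_max * ppfd / (ppfd + params.k_npq) if ppfd > 0 else 0.0
    qp_ss = 1.0 / (1.0 + ppfd / params.k_qp)
    return npq_ss, qp_ss


def _phase_entries(
    params: GenotypeParams, protocol: LightProtocol
) -> list[tuple[float, float, float, float]]:
    """Per phase: (t_start, npq_entry, npq_target, rate b)."""
    entries = []
    t0, npq_entry = 0.0, 0.0
    for phase in protocol.phases:
        target, _ = steady_state_targets(params, phase.ppfd)
        b = params.b_induction if target > npq_entry else params.b_relaxation
        entries.append((t0, npq_entry, target, b))
        npq_entry = target + (npq_entry - target) * np.exp(-b * phase.duration_s)
        t0 += phase.duration_s
    return entries


def npq_at_times(
    params: GenotypeParams, protocol: LightProtocol, times_s: np.ndarray
) -> np.ndarray:
    """Exact model NPQ at arbitrary times within the protocol."""
    times_s = np.asarray(times_s, dtype=float)
    entries = _phase_entries(params, protocol)
    starts = [e[0] for e in entries]
    out = np.empty_like(times_s)
    idx = np.clip(np.searchsorted(starts, times_s, side="right") - 1, 0, len(entries) - 1)
    for k, (t0, entry, target, b) in enumerate(entries):
        sel = idx == k
        if sel.any():
            out[sel] = target + (entry - target) * np.exp(-b * (times_s[sel] - t0))
    return out


def simulate_npq_trajectory(
    params: GenotypeParams, protocol: LightProtocol, dt: float = 1.0
) -> pd.DataFrame:
    """True NPQ time series on a uniform grid of step ``dt`` seconds.

    Within each phase NPQ relaxes exponentially from its phase-entry
    value toward the steady-state target of the phase PPFD, at the
    induction rate when the target lies above the entry value and the
    relaxation rate otherwise.  The trajectory is continuous and starts
    at NPQ = 0.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    times = np.arange(0.0, protocol.total_duration_s + dt / 2, dt)
    return pd.DataFrame({"time_s": times, "npq": npq_at_times(params, protocol, times)})


@dataclass
class GroundTruth:
    """Everything the simulator knows: parameters and per-pulse truth.

    ``per_pulse`` has one row per (sample, pulse) with the exact model
    values of every quantity the analysis pipeline later estimates.
    """

    params_by_sample: dict[int, GenotypeParams]
    per_pulse: pd.DataFrame

    def for_sample(self, sample_id: int) -> pd.DataFrame:
        return self.per_pulse[self.per_pulse["sample_id"] == sample_id]


def _true_pulse_table(
    layout: PlateLayout,
    params_by_sample: dict[int, GenotypeParams],
    protocol: LightProtocol,
) -> pd.DataFrame:
    pulses = pulse_schedule(protocol)
    rows = []
    for sid in sorted(layout.sections):
        p = params_by_sample[sid]
        times = np.array([pl.time_s for pl in pulses])
        npq_true = npq_at_times(p, protocol, times)
        for k, pl in enumerate(pulses):
            if pl.label == "dark":
                f_p, fm_p, fo_p = p.fo_dark, p.fm_dark, p.fo_dark
                npq_k, qp_k = 0.0, 1.0
            else:
                npq_k = float(npq_true[k])
                fm_p = p.fm_dark / (1.0 + npq_k)
                fo_p = estimate_fo_prime(p.fo_dark, p.fv_fm_true, fm_p)
                _, qp_k = steady_state_targets(p, pl.ppfd)
                f_p = fm_p - qp_k * (fm_p - fo_p)
            rows.append(
                {
                    "sample_id": sid,
                    "pulse_index": k,
                    "time_s": pl.time_s,
                    "ppfd": pl.ppfd,
                    "label": pl.label,
                    "npq": npq_k,
                    "f_prime": f_p,
                    "fm_prime": fm_p,
                    "fo_prime": fo_p,
                    "qp": qp_k,
                    "fv_fm": p.fv_fm_true,
                    "fvp_fmp": fvp_fmp(fo_p, fm_p),
                    "fqp_fmp": fqp_fmp(f_p, fm_p),
                }
            )
    return pd.DataFrame(rows)


def render_plate(
    layout: PlateLayout,
    params_by_sample: dict[int, GenotypeParams] | GenotypeParams,
    protocol: LightProtocol,
    seed: int = 0,
    background_level: float = 2.0,
    background_sd: float = 0.8,
) -> tuple[FrameStack, GroundTruth]:
    """Render the image stack for a full protocol run on one plate.

    ``params_by_sample`` maps sample_id -> GenotypeParams (a single
    GenotypeParams is broadcast to every section; a layout with genotype
    assignments may instead rely on ``GENOTYPE_PRESETS`` names).  Per
    pulse, leaf pixels take the model F'/Fm' values with multiplicative
    Gaussian noise of the genotype's ``noise_cv`` (truncated at zero);
    background pixels are drawn from a low-count noise floor.
    Deterministic for a fixed seed.
    """
    if isinstance(params_by_sample, GenotypeParams):
        params_by_sample = {sid: params_by_sample for sid in layout.sections}
    missing = set(layout.sections) - set(params_by_sample)
    if missing:
        raise ValueError(f"no GenotypeParams for samples {sorted(missing)}")

    truth_table = _true_pulse_table(layout, params_by_sample, protocol)
    pulses = pulse_schedule(protocol)
    n_pulses = len(pulses)
    h, w = layout.shape
    rng = np.random.default_rng(seed)
    frames = np.empty((n_pulses, 2, h, w), dtype=np.float64)
    # background noise floor, redrawn per frame
    for k in range(n_pulses):
        for role in range(2):
            frames[k, role] = np.clip(
                rng.normal(background_level, background_sd, size=(h, w)), 0.0, None
            )
    by_pulse = truth_table.set_index(["sample_id", "pulse_index"])
    for sid, (r, c, sh, sw) in layout.sections.items():
        cv = params_by_sample[sid].noise_cv
        for k in range(n_pulses):
            row = by_pulse.loc[(sid, k)]
            for role, value in enumerate((row["f_prime"], row["fm_prime"])):
                if cv > 0:
                    pix = value * (1.0 + cv * rng.standard_normal((sh, sw)))
                    np.clip(pix, 0.0, None, out=pix)
                else:
                    pix = np.full((sh, sw), value)
                frames[k, role, r:r + sh, c:c + sw] = pix
    metadata = pd.DataFrame(
        {
            "pulse_index": np.arange(n_pulses),
            "time_s": [p.time_s for p in pulses],
            "ppfd": [p.ppfd for p in pulses],
            "f_page": np.arange(n_pulses) * 2,
            "fm_page": np.arange(n_pulses) * 2 + 1,
            "label": [p.label for p in pulses],
        }
    )
    stack = FrameStack(frames=frames, metadata=metadata)
    return stack, GroundTruth(params_by_sample=params_by_sample, per_pulse=truth_table)


def write_dataset(
    stack: FrameStack,
    truth: GroundTruth | None,
    directory: str | Path,
    dtype: str = "uint16",
) -> dict[str, Path]:
    """Write a dataset to disk: multi-page TIFF, pulse CSV, ground-truth CSV.

    Pages are written in pulse order, the steady-state frame before the
    maximal frame for each pulse.  ``dtype`` selects the pixel format:
    ``"uint16"`` (instrument-like integer counts, values rounded) or
    ``"float32"``/``"float64"`` for lossless round-trips of model values.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {directory}: {exc}") from exc
    n_pulses, _, h, w = stack.frames.shape
    pages = stack.frames.reshape(n_pulses * 2, h, w)
    if dtype == "uint16":
        pages = np.clip(np.rint(pages), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    elif dtype in ("float32", "float64"):
        pages = pages.astype(dtype)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    paths = {
        "frames": directory / FRAMES_FILENAME,
        "pulses": directory / PULSES_FILENAME,
    }
    tifffile.imwrite(paths["frames"], pages)
    stack.metadata[PULSE_METADATA_COLUMNS].to_csv(paths["pulses"], index=False)
    if truth is not None:
        paths["ground_truth"] = directory / GROUND_TRUTH_FILENAME
        truth.per_pulse.to_csv(paths["ground_truth"], index=False)
    return paths


def simulate_gas_log(
    schedule: list[tuple[float, float, float]],
    tau_s: float = 25.0,
    noise_sd: tuple[float, float] = (0.0, 0.0),
    sample_interval_s: float = 15.0,
    duration_s: float | None = None,
    pressure_kpa: float = 101.3,
    pressure_noise_sd: float = 0.0,
    seed: int = 0,
) -> GasLog:
    """First-order chamber gas dynamics sampled like the real sensors.

    ``schedule`` lists (switch_time_s, o2_target mmol mol⁻¹, co2_target
    µmol mol⁻¹); the chamber starts equilibrated at the first entry's
    targets.  After each switch both gases approach the new targets
    exponentially with time constant ``tau_s``; additive Gaussian sensor
    noise with per-channel ``noise_sd`` is applied.  Deterministic given
    the seed.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be > 0")
    if not schedule:
        raise ValueError("schedule must contain at least one entry")
    schedule = sorted(schedule)
    if any(o2 <= 0 or co2 <= 0 for _, o2, co2 in schedule):
        raise ValueError("gas targets must be positive")
    if duration_s is None:
        duration_s = schedule[-1][0] + 10 * tau_s
    times = np.arange(0.0, duration_s + sample_interval_s / 2, sample_interval_s)

    def _series(targets: list[float]) -> np.ndarray:
        out = np.empty_like(times)
        x0 = targets[0]
        for i, (t_sw, _, _) in enumerate(schedule):
            t_end = schedule[i + 1][0] if i + 1 < len(schedule) else np.inf
            sel = (times >= t_sw) & (times < t_end)
            target = targets[i]
            out[sel] = target + (x0 - target) * np.exp(-(times[sel] - t_sw) / tau_s)
            x0 = target + (x0 - target) * np.exp(-(t_end - t_sw) / tau_s) if np.isfinite(t_end) else target
        out[times < schedule[0][0]] = targets[0]
        return out

    o2 = _series([s[1] for s in schedule])
    co2 = _series([s[2] for s in schedule])
    rng = np.random.default_rng(seed)
    if noise_sd[0] > 0:
        o2 = o2 + rng.normal(0.0, noise_sd[0], size=times.shape)
    if noise_sd[1] > 0:
        co2 = co2 + rng.normal(0.0, noise_sd[1], size=times.shape)
    pressure = np.full_like(times, pressure_kpa)
    if pressure_noise_sd > 0:
        pressure = pressure + rng.normal(0.0, pressure_noise_sd, size=times.shape)
    data = pd.DataFrame(
        {
            "time_s": times,
            "o2_mmol_mol": np.clip(o2, 0.0, None),
            "co2_umol_mol": np.clip(co2, 0.0, None),
            "pressure_kpa": np.clip(pressure, 0.0, None),
        }
    )[GAS_LOG_COLUMNS]
    return GasLog(data)
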