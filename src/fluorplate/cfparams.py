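"""PSII parameter engine: dark- and light-adapted quenching parameters.

Implements the standard pulse-amplitude-modulated fluorescence algebra on
per-ROI, per-pulse fluorescence means:

* Fv/Fm = (Fm - Fo)/Fm — maximum quantum efficiency of PSII (dark-adapted)
* Fv'/Fm' = (Fm' - Fo')/Fm' — maximum PSII efficiency in the light
* Fq'/Fm' = (Fm' - F')/Fm' — PSII operating efficiency (ΦPSII)
* NPQ = (Fm - Fm')/Fm' — non-photochemical quenching
* qP = (Fm' - F')/(Fm' - Fo') — photochemical quenching (= Fq'/Fv')
* qL = qP · Fo'/F' — fraction of open PSII centres (lake model)
* ETR = ΦPSII · PPFD · absorptance · 0.5 — linear electron transport rate

Fo' is rarely measured on imaging systems; the Oxborough–Baker estimator
Fo' = Fo / (Fv/Fm + Fo/Fm') is used by default, with a measured-Fo' input
path for instruments that provide one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DarkReference",
    "fv_fm",
    "estimate_fo_prime",
    "fvp_fmp",
    "fqp_fmp",
    "npq",
    "qp",
    "ql",
    "etr",
    "derive_cf_table",
    "CF_TABLE_COLUMNS",
    "DEFAULT_ABSORPTANCE",
]

#: Default leaf absorptance (fraction of incident PPFD absorbed).
DEFAULT_ABSORPTANCE = 0.84

CF_TABLE_COLUMNS = [
    "sample_id",
    "time_s",
    "ppfd",
    "fv_fm",
    "fvp_fmp",
    "fqp_fmp",
    "npq",
    "qp",
    "ql",
    "etr",
    "flags",
]


@dataclass(frozen=True)
class DarkReference:
    """Dark-adapted Fo/Fm reference for one sample (from the "dark" pulse)."""

    sample_id: int
    fo: float
    fm: float

    def __post_init__(self) -> None:
        if not (self.fm > self.fo > 0):
            raise ValueError(
                f"dark reference requires fm > fo > 0, got fo={self.fo}, fm={self.fm}"
            )

    @property
    def fv(self) -> float:
        return self.fm - self.fo

    @property
    def fv_fm(self) -> float:
        return self.fv / self.fm


def fv_fm(fo, fm):
    """Maximum quantum efficiency of PSII, (Fm - Fo)/Fm."""
    fo = np.asarray(fo, dtype=float)
    fm = np.asarray(fm, dtype=float)
    if np.any(fm <= 0):
        raise ValueError("fm must be > 0")
    out = (fm - fo) / fm
    if np.any(fo > fm):
        warnings.warn("fo > fm: negative Fv/Fm flagged", RuntimeWarning, stacklevel=2)
    return out if out.ndim else float(out)


def estimate_fo_prime(fo, fv_fm_value, fm_prime):
    """Light-adapted minimal fluorescence via the Oxborough–Baker estimator.

    Fo' = Fo / (Fv/Fm + Fo/Fm'); reduces to Fo when Fm' = Fm.
    """
    fo = np.asarray(fo, dtype=float)
    fv_fm_value = np.asarray(fv_fm_value, dtype=float)
    fm_prime = np.asarray(fm_prime, dtype=float)
    if np.any(fo <= 0) or np.any(fm_prime <= 0):
        raise ValueError("fo and fm_prime must be > 0")
    if np.any((fv_fm_value <= 0) | (fv_fm_value >= 1)):
        raise ValueError("fv_fm must lie in (0, 1)")
    out = fo / (fv_fm_value + fo / fm_prime)
    return out if out.ndim else float(out)


def fvp_fmp(fo_prime, fm_prime):
    """Maximum PSII efficiency in the light, (Fm' - Fo')/Fm'."""
    fo_prime = np.asarray(fo_prime, dtype=float)
    fm_prime = np.asarray(fm_prime, dtype=float)
    if np.any(fm_prime <= 0):
        raise ValueError("fm_prime must be > 0")
    out = (fm_prime - fo_prime) / fm_prime
    return out if out.ndim else float(out)


def fqp_fmp(f_prime, fm_prime):
    """PSII operating efficiency ΦPSII, (Fm' - F')/Fm'."""
    f_prime = np.asarray(f_prime, dtype=float)
    fm_prime = np.asarray(fm_prime, dtype=float)
    if np.any(fm_prime <= 0):
        raise ValueError("fm_prime must be > 0")
    out = (fm_prime - f_prime) / fm_prime
    return out if out.ndim else float(out)


def npq(fm, fm_prime):
    """Non-photochemical quenching, (Fm - Fm')/Fm'."""
    fm = np.asarray(fm, dtype=float)
    fm_prime = np.asarray(fm_prime, dtype=float)
    if np.any(fm <= 0) or np.any(fm_prime <= 0):
        raise ValueError("fm and fm_prime must be > 0")
    out = (fm - fm_prime) / fm_prime
    if np.any(out < 0):
        warnings.warn(
            "fm_prime > fm: negative NPQ flagged", RuntimeWarning, stacklevel=2
        )
    return out if out.ndim else float(out)


def qp(f_prime, fm_prime, fo_prime):
    """Photochemical quenching coefficient, (Fm' - F')/(Fm' - Fo')."""
    f_prime = np.asarray(f_prime, dtype=float)
    fm_prime = np.asarray(fm_prime, dtype=float)
    fo_prime = np.asarray(fo_prime, dtype=float)
    if np.any(fm_prime <= fo_prime):
        raise ValueError("fm_prime must exceed fo_prime (degenerate qP)")
    out = (fm_prime - f_prime) / (fm_prime - fo_prime)
    return out if out.ndim else float(out)


def ql(f_prime, fm_prime, fo_prime, variant: str = "standard"):
    """Fraction of open PSII centres under the lake model.

    The ``standard`` variant is qP · (Fo'/F'); the ``as_printed`` variant
    divides instead of multiplying, qP / (Fo'/F'), which can exceed 1 and
    triggers a range warning.  The standard form is the default because it
    keeps qL within [0, 1] on valid inputs.
    """
    f_prime = np.asarray(f_prime, dtype=float)
    if np.any(f_prime <= 0):
        raise ValueError("f_prime must be > 0")
    q = np.asarray(qp(f_prime, fm_prime, fo_prime))
    fo_prime = np.asarray(fo_prime, dtype=float)
    if variant == "standard":
        out = q * (fo_prime / f_prime)
    elif variant == "as_printed":
        out = q / (fo_prime / f_prime)
        if np.any(out > 1):
            warnings.warn(
                "as_printed qL exceeds 1 (outside [0, 1])", RuntimeWarning, stacklevel=2
            )
    else:
        raise ValueError(f"unknown qL variant {variant!r}")
    return out if out.ndim else float(out)


def etr(fq_fm_prime, ppfd, absorptance: float = DEFAULT_ABSORPTANCE,
        psii_fraction: float = 0.5):
    """Linear electron transport rate, µmol electrons m⁻² s⁻¹.

    ΦPSII × absorbed PPFD × the PSII/PSI energy-partition factor (0.5).
    """
    fq_fm_prime = np.asarray(fq_fm_prime, dtype=float)
    ppfd = np.asarray(ppfd, dtype=float)
    if not (0 < absorptance <= 1):
        raise ValueError("absorptance must lie in (0, 1]")
    if psii_fraction < 0:
        raise ValueError("psii_fraction must be >= 0")
    out = fq_fm_prime * (ppfd * absorptance) * psii_fraction
    return out if out.ndim else float(out)


def dark_references(records: pd.DataFrame) -> dict[int, DarkReference]:
    """Extract per-sample dark references from a pulse-record table.

    ``records`` must contain one row labelled ``"dark"`` per sample, with
    ``f_mean`` = Fo and ``fm_mean`` = Fm.
    """
    refs: dict[int, DarkReference] = {}
    dark = records[records["label"] == "dark"]
    for _, row in dark.iterrows():
        sid = int(row["sample_id"])
        if sid in refs:
            raise ValueError(f"sample {sid} has more than one dark pulse")
        refs[sid] = DarkReference(sid, float(row["f_mean"]), float(row["fm_mean"]))
    return refs


def derive_cf_table(
    records: pd.DataFrame,
    dark_refs: dict[int, DarkReference] | None = None,
    absorptance: float = DEFAULT_ABSORPTANCE,
    ql_variant: str = "standard",
    exclude_flagged: bool = True,
) -> pd.DataFrame:
    """Derive the full per-sample, per-pulse parameter table.

    Parameters
    ----------
    records
        Tidy pulse-record table with columns ``sample_id, time_s, ppfd,
        label, f_mean, fm_mean`` and optional ``flags``.
    dark_refs
        Per-sample dark references; derived from the ``"dark"``-labelled
        rows of ``records`` when omitted.
    absorptance
        Leaf absorptance used for ETR.
    ql_variant
        ``"standard"`` or ``"as_printed"`` (see :func:`ql`).
    exclude_flagged
        Drop input rows carrying quality flags (e.g. fm < f) rather than
        propagating them into the table.

    Returns
    -------
    DataFrame with one row per (sample, pulse) and the columns of
    ``CF_TABLE_COLUMNS``.  Dark rows carry ``fv_fm`` and NaN light-adapted
    fields; lit rows carry the light-adapted parameters.
    """
    required = {"sample_id", "time_s", "ppfd", "label", "f_mean", "fm_mean"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"pulse-record table missing columns: {sorted(missing)}")
    if dark_refs is None:
        dark_refs = dark_references(records)
    samples = sorted(records["sample_id"].unique())
    absent = [int(s) for s in samples if s not in dark_refs]
    if absent:
        raise ValueError(f"missing dark reference for samples {absent}")

    if "flags" not in records.columns:
        records = records.assign(flags="")
    rows = []
    for _, rec in records.sort_values(["sample_id", "time_s"]).iterrows():
        sid = int(rec["sample_id"])
        ref = dark_refs[sid]
        flags = str(rec.get("flags", "") or "")
        if flags and exclude_flagged:
            continue
        base = {
            "sample_id": sid,
            "time_s": float(rec["time_s"]),
            "ppfd": float(rec["ppfd"]),
            "flags": flags,
        }
        if rec["label"] == "dark":
            rows.append({**base, "fv_fm": ref.fv_fm, "fvp_fmp": np.nan,
                         "fqp_fmp": np.nan, "npq": np.nan, "qp": np.nan,
                         "ql": np.nan, "etr": np.nan})
            continue
        f_p, fm_p = float(rec["f_mean"]), float(rec["fm_mean"])
        fo_p = estimate_fo_prime(ref.fo, ref.fv_fm, fm_p)
        phi = fqp_fmp(f_p, fm_p)
        rows.append({
            **base,
            "fv_fm": ref.fv_fm,
            "fvp_fmp": fvp_fmp(fo_p, fm_p),
            "fqp_fmp": phi,
            "npq": npq(ref.fm, fm_p),
            "qp": qp(f_p, fm_p, fo_p),
            "ql": ql(f_p, fm_p, fo_p, variant=ql_variant),
            "etr": etr(phi, float(rec["ppfd"]), absorptance),
        })
    return pd.DataFrame(rows, columns=CF_TABLE_COLUMNS)
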