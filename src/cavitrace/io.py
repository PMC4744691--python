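"""Readers and writers for the four table kinds the pipeline consumes.

All files are delimited text (CSV by default) with a header row; column
names are mapped through keyword arguments rather than position because
acquisition-software exports vary.  Readers normalise to the package's
canonical representation: time in seconds and signed Ψ (negative MPa),
whatever the input convention.
"""

from __future__ import annotations

import importlib.resources
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    AEHit,
    AESeries,
    PsiSeries,
    SpeciesSummary,
    VulnMeasurement,
    plc_from_conductivity,
)

__all__ = [
    "read_hits",
    "write_hits",
    "read_psi",
    "write_psi",
    "read_vuln_table",
    "write_vuln_table",
    "read_species_summary",
    "write_species_summary",
    "load_reference_panel",
    "read_config",
]

PathLike = Union[str, Path]


def _canonical_psi(values: np.ndarray, convention: str, what: str) -> np.ndarray:
    """Map a Ψ column to signed MPa.

    convention: 'signed' (≤ 0 as stored), 'magnitude' (positive tensions),
    or 'auto' (accepted only when the column's sign is unambiguous).
    """
    values = np.asarray(values, dtype=float)
    if convention == "signed":
        return values
    if convention == "magnitude":
        return -np.abs(values)
    if convention == "auto":
        nonzero = values[values != 0]
        if nonzero.size == 0 or np.all(nonzero < 0):
            return values
        if np.all(nonzero > 0):
            return -values
        raise ValueError(
            f"{what}: mixed-sign Ψ column; pass psi_convention='signed' or "
            "'magnitude' explicitly"
        )
    raise ValueError(f"unknown Ψ convention {convention!r}")


def read_hits(
    path: PathLike,
    *,
    time_col: str = "time",
    amplitude_col: str = "amplitude_db",
    energy_col: Optional[str] = "energy",
    time_unit: str = "s",
    sample_id: Optional[str] = None,
    time_tolerance_s: float = 0.0,
    sep: str = ",",
) -> AESeries:
    """Read an AE hit log into an :class:`AESeries`.

    Parameters
    ----------
    time_unit : {'s', 'min'}
        Unit of the time column; minutes are converted to seconds.
    time_tolerance_s :
        Maximum allowed backwards step between consecutive raw rows.
        Out-of-order rows within the tolerance are re-sorted silently
        (buffered acquisition can reorder near-simultaneous hits); a
        larger backwards jump raises, naming the first offending row.
    """
    df = pd.read_csv(path, sep=sep)
    for col in (time_col, amplitude_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    bad = df[df[time_col].isna() | df[amplitude_col].isna()]
    if len(bad):
        # header is line 1, hence +2 for 1-based file line numbers
        lines = [int(i) + 2 for i in bad.index[:10]]
        warnings.warn(
            f"{path}: dropped {len(bad)} malformed row(s) at line(s) {lines}",
            stacklevel=2,
        )
        df = df.drop(bad.index)

    scale = {"s": 1.0, "min": 60.0}.get(time_unit)
    if scale is None:
        raise ValueError(f"time_unit must be 's' or 'min', got {time_unit!r}")
    times = df[time_col].to_numpy(dtype=float) * scale

    steps = np.diff(times)
    if np.any(steps < -time_tolerance_s):
        row = int(np.argmax(steps < -time_tolerance_s)) + 1
        raise ValueError(
            f"{path}: non-monotonic timestamps beyond tolerance at data row "
            f"{row + 1} (file line {row + 2})"
        )

    energies = None
    if energy_col is not None and energy_col in df.columns:
        energies = df[energy_col].to_numpy(dtype=float)
    amps = df[amplitude_col].to_numpy(dtype=float)

    order = np.argsort(times, kind="stable")
    hits = [
        AEHit(
            time_s=float(times[i]),
            amplitude_db=float(amps[i]),
            energy=float(energies[i]) if energies is not None else None,
        )
        for i in order
    ]
    return AESeries(hits=hits, sample_id=sample_id or Path(path).stem)


def write_hits(series: AESeries, path: PathLike) -> None:
    rows = {
        "time": series.times_s,
        "amplitude_db": series.amplitudes_db,
    }
    energies = [h.energy for h in series.hits]
    if any(e is not None for e in energies):
        rows["energy"] = [np.nan if e is None else e for e in energies]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_psi(
    path: PathLike,
    *,
    time_col: str = "time",
    psi_col: str = "psi_mpa",
    se_col: Optional[str] = "se_mpa",
    time_unit: str = "s",
    psi_convention: str = "auto",
    sep: str = ",",
) -> PsiSeries:
    """Read a water-potential series; Ψ is canonicalised to signed MPa."""
    df = pd.read_csv(path, sep=sep)
    for col in (time_col, psi_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    scale = {"s": 1.0, "min": 60.0}.get(time_unit)
    if scale is None:
        raise ValueError(f"time_unit must be 's' or 'min', got {time_unit!r}")
    times = df[time_col].to_numpy(dtype=float) * scale
    psi = _canonical_psi(df[psi_col].to_numpy(dtype=float), psi_convention, str(path))
    ses = (
        df[se_col].to_numpy(dtype=float)
        if se_col is not None and se_col in df.columns
        else None
    )
    order = np.argsort(times, kind="stable")
    readings = []
    for i in order:
        if ses is not None and np.isfinite(ses[i]):
            readings.append((float(times[i]), float(psi[i]), float(ses[i])))
        else:
            readings.append((float(times[i]), float(psi[i])))
    return PsiSeries(readings=readings)


def write_psi(psi: PsiSeries, path: PathLike) -> None:
    ses = [r[2] if len(r) > 2 else np.nan for r in psi.readings]
    df = pd.DataFrame(
        {"time": psi.times_s, "psi_mpa": psi.psi_mpa, "se_mpa": ses}
    )
    if df["se_mpa"].isna().all():
        df = df.drop(columns="se_mpa")
    df.to_csv(path, index=False)


def read_vuln_table(
    path: PathLike,
    *,
    psi_col: str = "psi_mpa",
    plc_col: str = "plc_percent",
    k_native_col: str = "k_native",
    k_max_col: str = "k_max",
    sample_col: Optional[str] = "sample_id",
    psi_convention: str = "auto",
    sep: str = ",",
) -> list[VulnMeasurement]:
    """Read vulnerability data given either as (Ψ, PLC) or as
    (Ψ, k_native, k_max); conductivities are converted to PLC."""
    df = pd.read_csv(path, sep=sep)
    if psi_col not in df.columns:
        raise ValueError(f"{path}: missing required column {psi_col!r}")
    psi = _canonical_psi(df[psi_col].to_numpy(dtype=float), psi_convention, str(path))
    if plc_col in df.columns:
        plc = np.clip(df[plc_col].to_numpy(dtype=float), 0.0, 100.0)
    elif k_native_col in df.columns and k_max_col in df.columns:
        plc = np.array(
            [
                plc_from_conductivity(kn, km)
                for kn, km in zip(df[k_native_col], df[k_max_col])
            ]
        )
    else:
        raise ValueError(
            f"{path}: need either {plc_col!r} or both {k_native_col!r} and "
            f"{k_max_col!r}"
        )
    samples = (
        df[sample_col].astype(str).tolist()
        if sample_col is not None and sample_col in df.columns
        else [None] * len(df)
    )
    return [
        VulnMeasurement(psi_mpa=float(p), plc_percent=float(c), sample_id=s)
        for p, c, s in zip(psi, plc, samples)
    ]


def write_vuln_table(data: Sequence[VulnMeasurement], path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "psi_mpa": [m.psi_mpa for m in data],
            "plc_percent": [m.plc_percent for m in data],
            "sample_id": [m.sample_id for m in data],
        }
    )
    if df["sample_id"].isna().all():
        df = df.drop(columns="sample_id")
    df.to_csv(path, index=False)


_SUMMARY_COLS = [
    "species",
    "clade",
    "p50_mpa",
    "p50_ci_lo",
    "p50_ci_hi",
    "n_p50",
    "pmaxrate_mpa",
    "pmax_ci_lo",
    "pmax_ci_hi",
    "n_pmax",
]


def read_species_summary(
    path: PathLike, *, psi_convention: str = "auto", sep: str = ","
) -> list[SpeciesSummary]:
    """Read a species summary table (P50, P_maxrate, CIs, n, clade)."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("species", "p50_mpa") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    def _opt(row, col, cast=float):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return cast(row[col])

    psi_cols = [
        c
        for c in ("p50_mpa", "p50_ci_lo", "p50_ci_hi", "pmaxrate_mpa", "pmax_ci_lo", "pmax_ci_hi")
        if c in df.columns
    ]
    stacked = df[psi_cols].to_numpy(dtype=float).ravel()
    finite = stacked[np.isfinite(stacked)]
    if psi_convention == "magnitude":
        flip = True
    elif psi_convention == "signed":
        flip = False
    elif psi_convention == "auto":
        if np.all(finite <= 0):
            flip = False
        elif np.all(finite >= 0):
            flip = True
        else:
            raise ValueError(
                f"{path}: mixed-sign Ψ columns; pass psi_convention explicitly"
            )
    else:
        raise ValueError(f"unknown Ψ convention {psi_convention!r}")
    if flip:
        df = df.copy()
        df[psi_cols] = -df[psi_cols].abs()

    out = []
    for _, row in df.iterrows():
        out.append(
            SpeciesSummary(
                species=str(row["species"]),
                clade=str(row.get("clade", "angiosperm")),
                p50_mpa=float(row["p50_mpa"]),
                p50_ci_lo=_opt(row, "p50_ci_lo"),
                p50_ci_hi=_opt(row, "p50_ci_hi"),
                n_p50=_opt(row, "n_p50", int),
                pmaxrate_mpa=_opt(row, "pmaxrate_mpa"),
                pmax_ci_lo=_opt(row, "pmax_ci_lo"),
                pmax_ci_hi=_opt(row, "pmax_ci_hi"),
                n_pmax=_opt(row, "n_pmax", int),
            )
        )
    return out


def write_species_summary(
    summaries: Sequence[SpeciesSummary], path: PathLike
) -> None:
    df = pd.DataFrame(
        [{c: getattr(s, c) for c in _SUMMARY_COLS} for s in summaries]
    )
    df.to_csv(path, index=False)


def load_reference_panel() -> list[SpeciesSummary]:
    """The packaged reference panel: published species-level means, 95% CIs
    and sample sizes of hydraulic P50 and acoustic P_maxrate for 16 woody
    species and three apple cultivars (15 angiosperm entries, 3 conifers).

    This is the dataset behind the cross-method regression; raw AE logs and
    PLC measurements for these species are not published, so the panel is
    the package's only non-synthetic fixture.
    """
    ref = importlib.resources.files("cavitrace.data") / "species_panel.csv"
    with importlib.resources.as_file(ref) as p:
        return read_species_summary(p)


def read_config(path: PathLike) -> dict:
    """Parse a plain-text ``key = value`` config file.

    Values are coerced to int/float/bool where possible; '#' starts a
    comment.  TOML files (suffix .toml) are parsed with :mod:`tomllib`.
    """
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            return tomllib.load(fh)
    out: dict = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        for cast in (int, float):
            try:
                out[key] = cast(value)
                break
            except ValueError:
                continue
        else:
            if value.lower() in ("true", "false"):
                out[key] = value.lower() == "true"
            else:
                out[key] = value.strip("'\"")
    return out
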