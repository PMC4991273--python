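"""Readers, writers and run configuration for the plain-text file formats.

All formats are explicit-header CSV with ``#`` comment lines:

* decay / IRF files: ``time_ns,counts``
* spectra files: ``wavelength_nm`` plus one intensity column per titration
  point, with a manifest CSV mapping column names to DNA concentrations
* CV files: ``potential_V,current_A`` with metadata (scan rate, reference)
  in ``# key = value`` comment lines
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding import EmissionSpectrum
from .decay import DecayTrace, InstrumentResponse, TimeAxis
from .electrochem import (
    FC_TO_NHE_V,
    GUANINE_EOX_V,
    NHE_ABSOLUTE_V,
    Voltammogram,
)

__all__ = [
    "ParseError",
    "RunConfig",
    "load_config",
    "read_decay",
    "read_irf",
    "write_trace",
    "read_spectra",
    "write_spectra",
    "read_cv",
    "write_cv",
    "report",
    "write_report",
]


class ParseError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Analysis constants, every one overridable from YAML/JSON or CLI flags."""

    guanine_eox_v: float = GUANINE_EOX_V
    fc_offset_v: float = FC_TO_NHE_V
    nhe_absolute_v: float = NHE_ABSOLUTE_V
    chisq_dof_policy: int = 200
    significance: float = 0.05
    free_dye_tau_short: float = 1.28   # ns, morpholino-substituted dye class
    free_dye_tau_long: float = 15.75   # ns, propyl-substituted dye class
    integration_band: tuple[float, float] = (584.0, 634.0)
    seed: int = 0


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ParseError(f"config file {path} must contain a mapping")
    data.update(overrides)
    if "integration_band" in data:
        data["integration_band"] = tuple(data["integration_band"])
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ParseError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _read_columns(path: Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    bad = df.index[df[required].isna().any(axis=1)]
    if len(bad):
        # +2: one for the header line, one for 0- vs 1-based numbering
        raise ParseError(f"{path}: malformed value(s) near line(s) {[int(i) + 2 for i in bad[:5]]}")
    return df


def read_decay(path: str | Path, label: str | None = None, meta: dict | None = None) -> DecayTrace:
    path = Path(path)
    df = _read_columns(path, ["time_ns", "counts"])
    axis = TimeAxis.from_times(df["time_ns"].to_numpy())
    return DecayTrace(
        axis=axis,
        counts=df["counts"].to_numpy(dtype=float),
        label=label if label is not None else path.stem,
        meta=meta or {},
    )


def read_irf(path: str | Path) -> InstrumentResponse:
    df = _read_columns(Path(path), ["time_ns", "counts"])
    axis = TimeAxis.from_times(df["time_ns"].to_numpy())
    return InstrumentResponse(axis=axis, counts=df["counts"].to_numpy(dtype=float))


def write_trace(path: str | Path, obj: DecayTrace | InstrumentResponse, comments: list[str] | None = None) -> None:
    lines = [f"# {c}" for c in comments or []]
    lines.append("time_ns,counts")
    for t, c in zip(obj.axis.times, obj.counts):
        lines.append(f"{t:.9g},{c:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectra(path: str | Path, manifest: str | Path) -> list[EmissionSpectrum]:
    """Spectra CSV (wavelength_nm + intensity columns) plus a manifest.

    Manifest columns: ``column,dna_conc_M`` and optionally ``dye_conc_M``.
    """
    df = _read_columns(Path(path), ["wavelength_nm"])
    man = _read_columns(Path(manifest), ["column", "dna_conc_M"])
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    spectra = []
    for _, row in man.iterrows():
        col = str(row["column"])
        if col not in df.columns:
            raise ParseError(f"{manifest}: column {col!r} not present in {path}")
        spectra.append(
            EmissionSpectrum(
                wavelength=wl,
                intensity=df[col].to_numpy(dtype=float),
                dna_conc=float(row["dna_conc_M"]),
                dye_conc=float(row.get("dye_conc_M", 0.0) or 0.0),
            )
        )
    return spectra


def write_spectra(path: str | Path, manifest: str | Path, spectra: list[EmissionSpectrum]) -> None:
    cols = {"wavelength_nm": spectra[0].wavelength}
    man_rows = []
    for i, s in enumerate(spectra):
        name = f"point{i:02d}"
        cols[name] = s.intensity
        man_rows.append({"column": name, "dna_conc_M": s.dna_conc, "dye_conc_M": s.dye_conc})
    pd.DataFrame(cols).to_csv(path, index=False)
    pd.DataFrame(man_rows).to_csv(manifest, index=False)


def read_cv(path: str | Path) -> Voltammogram:
    path = Path(path)
    meta: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if line.startswith("#") and "=" in line:
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
    df = _read_columns(path, ["potential_V", "current_A"])
    if "scan_rate_V_s" not in meta:
        raise ParseError(f"{path}: missing '# scan_rate_V_s = ...' metadata line")
    return Voltammogram(
        potential=df["potential_V"].to_numpy(dtype=float),
        current=df["current_A"].to_numpy(dtype=float),
        scan_rate=float(meta["scan_rate_V_s"]),
        reference=meta.get("reference", "vs Fc+/Fc"),
    )


def write_cv(path: str | Path, v: Voltammogram) -> None:
    lines = [
        f"# scan_rate_V_s = {v.scan_rate:.9g}",
        f"# reference = {v.reference}",
        "potential_V,current_A",
    ]
    for E, i in zip(v.potential, v.current):
        lines.append(f"{E:.9g},{i:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(x) for x in obj]
    if isinstance(obj, (bool, int, str)) or obj is None:
        return obj
    if isinstance(obj, float):
        return obj
    return str(obj)


def report(results, config: RunConfig | None = None) -> dict:
    """Serialise any analysis result (dataclass or mapping) to a stable JSON schema."""
    out = {"results": _to_jsonable(results)}
    if config is not None:
        cfg = _to_jsonable(config)
        out["config"] = cfg
        out["config_hash"] = hashlib.md5(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:12]
    return out


def write_report(path: str | Path, results, config: RunConfig | None = None) -> None:
    Path(path).write_text(json.dumps(report(results, config), indent=2, sort_keys=True) + "\n")
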