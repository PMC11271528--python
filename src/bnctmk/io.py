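"""File formats, run configuration and reproducibility manifests.

Formats (all plain text):

* spectrum: 2-column CSV ``y_keVum,density``, ``#`` comments allowed;
* survival data: CSV ``dose_Gy,surviving_fraction[,sd]``;
* pit records: CSV ``cell_id,phase,area_um2,pit_count`` with a YAML sidecar
  holding ``background_density``, ``administered_ppm``,
  ``expected_density_100`` and the efficiency preset or value;
* posterior samples: CSV, one column per parameter; summaries: JSON.

Every command writes a ``manifest.json`` (config SHA-256, seed, package
version) sufficient to reproduce deterministic outputs bit for bit.
Numeric file output keeps at least 6 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .boron import EFFICIENCY_PRESETS, CellPitRecord, PitField, KNOWN_PHASES
from .mcmc import Posterior, SurvivalDataset
from .microdosimetry import DomainGeometry, LinealEnergySpectrum

__all__ = [
    "ParseError",
    "RunConfig",
    "read_spectrum",
    "write_spectrum",
    "read_survival_csv",
    "write_survival_csv",
    "read_pit_field",
    "write_pit_field",
    "write_posterior",
    "write_manifest",
    "resolve_efficiency",
    "get_logger",
]

logger = logging.getLogger("bnctmk")
FLOAT_FMT = "%.8g"


def get_logger() -> logging.Logger:
    if not logger.handlers:
        handler = logging.StreamHandler()  # stderr
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


class ParseError(ValueError):
    """Malformed input file; message names the file and offending line."""


def _read_table(path, required: tuple, optional: tuple = ()) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pandas raises several types for bad CSV
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}; have {list(df.columns)}")
    numeric = [c for c in required + optional if c in df.columns and c != "cell_id" and c != "phase"]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad or coerced.isna().any():
            rows = bad or df.index[coerced.isna()].tolist()
            # +2: header line plus 1-based numbering
            raise ParseError(
                f"{path}: non-numeric or missing value in column {col!r} "
                f"at line(s) {[int(i) + 2 for i in rows[:5]]}"
            )
        df[col] = coerced
    return df


def read_spectrum(path) -> LinealEnergySpectrum:
    df = _read_table(path, ("y_keVum", "density"))
    return LinealEnergySpectrum(df["y_keVum"].to_numpy(), df["density"].to_numpy()).normalize()


def write_spectrum(spectrum: LinealEnergySpectrum, path) -> None:
    pd.DataFrame({"y_keVum": spectrum.y_grid, "density": spectrum.density}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_survival_csv(path) -> SurvivalDataset:
    df = _read_table(path, ("dose_Gy", "surviving_fraction"), ("sd",))
    sf = df["surviving_fraction"].to_numpy(dtype=float)
    if np.any(sf <= 0):
        raise ParseError(f"{path}: surviving fractions must be positive")
    sd = df["sd"].to_numpy(dtype=float) if "sd" in df.columns else None
    return SurvivalDataset(
        doses=df["dose_Gy"].to_numpy(dtype=float), neg_log_sf=-np.log(sf), sd=sd
    )


def write_survival_csv(dataset: SurvivalDataset, path) -> None:
    df = pd.DataFrame(
        {
            "dose_Gy": dataset.doses,
            "surviving_fraction": np.exp(-dataset.neg_log_sf),
        }
    )
    if dataset.sd is not None:
        df["sd"] = dataset.sd
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def resolve_efficiency(value) -> tuple:
    """An efficiency given as a preset name or a number → (fraction, note)."""
    if isinstance(value, str):
        if value not in EFFICIENCY_PRESETS:
            raise ValueError(
                f"unknown efficiency preset {value!r}; choose from {sorted(EFFICIENCY_PRESETS)}"
            )
        return EFFICIENCY_PRESETS[value], f"preset {value}"
    return float(value), "explicit value"


def read_pit_field(csv_path, sidecar_path) -> tuple:
    """Pit CSV + YAML sidecar → (PitField, list of excluded unknown-label rows)."""
    df = _read_table(csv_path, ("cell_id", "phase", "area_um2", "pit_count"))
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    for key in ("background_density", "administered_ppm", "expected_density_100", "efficiency_ion"):
        if key not in meta:
            raise ParseError(f"{sidecar_path}: missing required key {key!r}")
    eff, note = resolve_efficiency(meta["efficiency_ion"])
    records, excluded = [], []
    for _, row in df.iterrows():
        phase = str(row["phase"]) if pd.notna(row["phase"]) else "unknown"
        if phase not in KNOWN_PHASES:
            excluded.append((str(row["cell_id"]), phase))
            continue
        records.append(
            CellPitRecord(
                cell_id=str(row["cell_id"]),
                phase_label=phase,
                area=float(row["area_um2"]),
                pit_count=int(row["pit_count"]),
            )
        )
    if not records:
        raise ParseError(f"{csv_path}: no usable cell records")
    fld = PitField(
        records=tuple(records),
        background_density=float(meta["background_density"]),
        administered_ppm=float(meta["administered_ppm"]),
        expected_density_100=float(meta["expected_density_100"]),
        efficiency_ion=eff,
        efficiency_note=note,
    )
    return fld, excluded


def write_pit_field(fld: PitField, csv_path, sidecar_path) -> None:
    pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in fld.records],
            "phase": [r.phase_label for r in fld.records],
            "area_um2": [r.area for r in fld.records],
            "pit_count": [r.pit_count for r in fld.records],
        }
    ).to_csv(csv_path, index=False, float_format=FLOAT_FMT)
    meta = {
        "background_density": float(fld.background_density),
        "administered_ppm": float(fld.administered_ppm),
        "expected_density_100": float(fld.expected_density_100),
        "efficiency_ion": float(fld.efficiency_ion),
        "efficiency_note": fld.efficiency_note,
    }
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def write_posterior(posterior: Posterior, samples_path, summary_path, summary: dict) -> None:
    pd.DataFrame(posterior.samples, columns=list(posterior.param_names)).to_csv(
        samples_path, index=False, float_format=FLOAT_FMT
    )
    payload = {
        "summary": summary,
        "acceptance_rate": posterior.acceptance_rate,
        "seed": posterior.seed,
        "prior_bounds": [list(b) for b in posterior.prior_bounds],
        "sigma": posterior.sigma,
        "n_iter": posterior.n_iter,
        "burn_in": posterior.burn_in,
        "thin": posterior.thin,
    }
    Path(summary_path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass
class RunConfig:
    """One YAML config shared by all commands; everything overridable.

    Physical defaults: y0 = 250 keV/μm, domain r_d = 0.5 μm, ρ = 1 g/cm³;
    reference quality given either as a spectrum file or a direct z1D*.
    """

    seed: int = 0
    output_dir: str = "out"
    r_d: float = 0.5
    rho: float = 1.0
    y0: float = 250.0
    efficiency_ion: Any = None  # preset name or number; required for boron steps
    reference_z1d: Optional[float] = 0.698
    reference_spectrum: Optional[str] = None
    mixture: Mapping[str, float] = field(
        default_factory=lambda: {"G1/S": 0.549, "S/G2/M": 0.451}
    )
    mcmc: Mapping[str, Any] = field(default_factory=dict)
    raw: Mapping[str, Any] = field(default_factory=dict)

    @property
    def geometry(self) -> DomainGeometry:
        return DomainGeometry(r_d=self.r_d, rho=self.rho)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        geo = data.get("geometry", {})
        return cls(
            seed=int(data.get("seed", 0)),
            output_dir=str(data.get("output_dir", "out")),
            r_d=float(geo.get("r_d", 0.5)),
            rho=float(geo.get("rho", 1.0)),
            y0=float(data.get("y0", 250.0)),
            efficiency_ion=data.get("efficiency_ion"),
            reference_z1d=data.get("reference", {}).get("z1d_star", 0.698)
            if "reference" in data
            else data.get("reference_z1d", 0.698),
            reference_spectrum=data.get("reference", {}).get("spectrum")
            if "reference" in data
            else data.get("reference_spectrum"),
            mixture=data.get("mixture", {"G1/S": 0.549, "S/G2/M": 0.451}),
            mcmc=data.get("mcmc", {}),
            raw=data,
        )


def write_manifest(out_dir, command: str, config: Mapping[str, Any], seed) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    canonical = yaml.safe_dump(_jsonable(config), sort_keys=True)
    manifest = {
        "command": command,
        "seed": seed,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "config": _jsonable(config),
        "bnctmk_version": __version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
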