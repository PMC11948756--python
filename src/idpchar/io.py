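"""Tabular and FASTA I/O, run configuration and report bundling.

All tabular dialects are comma-separated UTF-8 with a mandatory header row
and "." decimal separator.  Units are resolved at parse time into the
canonical internal system (µM, seconds, °C, Å, kDa); exposure times accept
"10 s", "1 min", "2.5 h" or bare seconds.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .binding import TitrationSeries
from .exceptions import FormatError, ValidationError
from .hdx import ExchangeControls, PeptideUptake
from .hydro import HydroSpecies
from .seqfeat import SequenceRecord
from .thermal import MeltCurve

__all__ = [
    "RunConfig", "ReportBundle", "parse_exposure_seconds",
    "read_titration_table", "write_titration_table",
    "read_hdx_cluster_table", "write_hdx_cluster_table",
    "read_fasta", "write_fasta",
    "read_melt_curve", "write_melt_curve",
    "read_species_table", "read_sec_standards",
]

_EXPOSURE_UNITS = {"s": 1.0, "sec": 1.0, "seconds": 1.0,
                   "min": 60.0, "m": 60.0, "h": 3600.0, "hr": 3600.0}

#: Control-state labels of the HDX flat dialect.
HDX_CONTROL_STATES = ("FD", "T0")


def parse_exposure_seconds(value) -> float:
    """Normalize an exposure time ('10 s', '1 min', '2.5 h', 10) to seconds."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    text = str(value).strip()
    m = re.fullmatch(r"([0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)\s*([a-zA-Z]*)", text)
    if not m:
        raise FormatError(f"cannot parse exposure time {value!r}")
    num, unit = float(m.group(1)), m.group(2).lower()
    if unit == "":
        return num
    if unit not in _EXPOSURE_UNITS:
        raise FormatError(f"unknown exposure unit {unit!r} in {value!r}")
    return num * _EXPOSURE_UNITS[unit]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# titrations

def write_titration_table(series: TitrationSeries, path) -> None:
    df = pd.DataFrame({"ligand_conc_um": series.ligand_concs})
    for i in range(series.n_replicates):
        df[f"signal_rep{i + 1}"] = series.signals[:, i]
    df.insert(0, "probe_conc_um", series.probe_conc)
    df.insert(1, "signal_kind", series.signal_kind)
    df.to_csv(path, index=False)


def read_titration_table(path, dialect: dict | None = None) -> TitrationSeries:
    """Load a titration CSV.

    ``dialect`` may remap column names: keys ``ligand``, ``probe``,
    ``signal_prefix`` (default ``ligand_conc_um``, ``probe_conc_um``,
    ``signal_rep``).  At least one signal column is required.
    """
    path = Path(path)
    dialect = dialect or {}
    ligand_col = dialect.get("ligand", "ligand_conc_um")
    probe_col = dialect.get("probe", "probe_conc_um")
    prefix = dialect.get("signal_prefix", "signal_rep")
    df = pd.read_csv(path)
    _require_columns(df, [ligand_col], path)
    signal_cols = [c for c in df.columns if c.startswith(prefix)]
    if not signal_cols:
        raise FormatError(f"{path}: no signal columns with prefix {prefix!r}")
    if (df[ligand_col] < 0).any():
        raise ValidationError(f"{path}: negative ligand concentration")
    df = df.sort_values(ligand_col, kind="stable")
    probe = float(df[probe_col].iloc[0]) if probe_col in df.columns else float(dialect.get("probe_conc_um", 0))
    kind = str(df["signal_kind"].iloc[0]) if "signal_kind" in df.columns else dialect.get("signal_kind", "mP")
    return TitrationSeries(probe_conc=probe,
                           ligand_concs=df[ligand_col].to_numpy(),
                           signals=df[signal_cols].to_numpy(),
                           signal_kind=kind)


# ---------------------------------------------------------------------------
# HDX flat dialect

HDX_COLUMNS = ["protein", "start", "end", "sequence", "state",
               "exposure_s", "replicate", "centroid_mass_da"]


def write_hdx_cluster_table(df: pd.DataFrame, path) -> None:
    df[HDX_COLUMNS].to_csv(path, index=False)


def read_hdx_cluster_table(path):
    """Parse the flat HDX dialect into uptake records and controls.

    Returns ``(states, controls, flags)`` where ``states`` maps state name →
    {peptide key → PeptideUptake}, ``controls`` maps peptide key →
    ExchangeControls, and ``flags`` lists peptide keys that lack control
    rows (flagged, not fatal).
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, HDX_COLUMNS, path)
    if (df["end"] < df["start"]).any():
        bad = df.loc[df["end"] < df["start"], "sequence"].iloc[0]
        raise ValidationError(f"{path}: peptide {bad!r} has end < start")
    df = df.copy()
    df["exposure_s"] = df["exposure_s"].map(parse_exposure_seconds)

    states: dict[str, dict] = {}
    mins: dict = {}
    maxs: dict = {}
    for (seq, start, end, state), group in df.groupby(
            ["sequence", "start", "end", "state"], sort=True):
        key = (seq, int(start), int(end))
        if state == "T0":
            mins[key] = group["centroid_mass_da"].to_numpy()
        elif state == "FD":
            maxs[key] = group["centroid_mass_da"].to_numpy()
        else:
            obs = {float(t): g["centroid_mass_da"].to_numpy()
                   for t, g in group.groupby("exposure_s")}
            states.setdefault(state, {})[key] = PeptideUptake(
                sequence=seq, start=int(start), end=int(end),
                state=state, observations=obs)
    all_keys = {k for d in states.values() for k in d}
    controls = {}
    missing = []
    for key in sorted(all_keys):
        if key in mins and key in maxs:
            controls[key] = ExchangeControls(m_min=mins[key], m_max=maxs[key])
        else:
            missing.append(key)
    return states, controls, missing


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[SequenceRecord]:
    """Read one or more FASTA records; UniProt-style accessions captured."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        m = re.match(r"^(?:sp|tr)\|([^|]+)\|", rec.id)
        if m:
            accession = m.group(1)
        records.append(SequenceRecord(residues=str(rec.seq), accession=accession))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.accession or 'seq'}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# melts / AUC species / SEC standards

def write_melt_curve(curve: MeltCurve, path) -> None:
    pd.DataFrame({"temp_c": curve.temperatures, "signal": curve.signal,
                  "direction": curve.direction, "channel": curve.channel
                  }).to_csv(path, index=False)


def read_melt_curve(path, direction=None, channel=None) -> MeltCurve:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["temp_c", "signal"], path)
    direction = direction or (str(df["direction"].iloc[0]) if "direction" in df.columns else "heating")
    channel = channel or (str(df["channel"].iloc[0]) if "channel" in df.columns else "dye")
    return MeltCurve(temperatures=df["temp_c"].to_numpy(),
                     signal=df["signal"].to_numpy(),
                     direction=direction, channel=channel)


def read_species_table(path) -> list[HydroSpecies]:
    """AUC species CSV: m_kda, vbar_ml_g[, ff0, s_svedberg]."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["m_kda", "vbar_ml_g"], path)
    out = []
    for _, row in df.iterrows():
        out.append(HydroSpecies(
            m_kda=float(row["m_kda"]), vbar=float(row["vbar_ml_g"]),
            ff0=float(row["ff0"]) if "ff0" in df.columns and pd.notna(row.get("ff0")) else None,
            s_svedberg=float(row["s_svedberg"]) if "s_svedberg" in df.columns
            and pd.notna(row.get("s_svedberg")) else None))
    return out


def read_sec_standards(path):
    """SEC standards CSV: ve_ml, rh_angstrom → list of (V_e, R_h)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["ve_ml", "rh_angstrom"], path)
    return list(zip(df["ve_ml"].astype(float), df["rh_angstrom"].astype(float)))


# ---------------------------------------------------------------------------
# run configuration / reports

_CONFIG_KEYS = {"seed", "inputs", "output_dir", "log_level", "params", "stages"}
_STOCHASTIC_STAGES = {"simulate"}


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML or dict).

    Unknown top-level keys are rejected; a seed is mandatory whenever a
    stochastic stage (simulation) is enabled.
    """

    seed: int | None = None
    inputs: dict = field(default_factory=dict)
    output_dir: str = "results"
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _CONFIG_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if _STOCHASTIC_STAGES & set(cfg.stages) and cfg.seed is None:
            raise ValidationError("seed required when a stochastic stage is enabled")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        blob = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Per-stage result tables plus a provenance block.

    ``tables`` maps stage name → DataFrame (every numeric column name must
    carry its unit suffix); ``parameters`` holds fitted-parameter records.
    """

    tables: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.provenance:
            from . import __version__
            self.provenance = {"package_version": __version__}

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "summary.txt", "w", encoding="utf-8") as fh:
            for k, v in self.provenance.items():
                fh.write(f"provenance.{k}={v}\n")
            for stage, rec in self.parameters.items():
                for k, v in rec.items():
                    fh.write(f"{stage}.{k}={v}\n")
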