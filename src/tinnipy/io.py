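"""Table formats and run configuration.

All tables are UTF-8, header-first CSV/TSV with unit-bearing column names.
Readers validate schemas and report offending row numbers (1-based, counting
the header as row 1).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from .records import CONDITIONS, TEST_TYPES
from .simulate import CohortSpec, SimConfig

TRIAL_COLUMNS = [
    "animal_id",
    "session_id",
    "test_type",
    "frequency_khz",
    "condition",
    "trial_index",
    "rms_baseline",
    "rms_startle",
]
TIMELINE_COLUMNS = ["animal_id", "arm", "phase", "week", "session_id"]
RESULT_COLUMNS = [
    "animal_id",
    "session_id",
    "phase",
    "week",
    "test_type",
    "frequency_khz",
    "n_used",
    "t",
    "p",
    "passed",
    "percent_suppression",
]
NEURON_COLUMNS = ["animal_id", "arm", "depth_um", "nominal_cf_khz", "spont_rate_hz"]
AUDIOGRAM_COLUMNS = ["animal_id", "arm", "ear", "frequency_khz", "threshold_db_spl", "phase"]
BDNF_COLUMNS = [
    "animal_id",
    "arm",
    "region",
    "side",
    "concentration_pg_ml",
    "total_protein_ug_ml",
    "dilution_factor",
]


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRIAL_COLUMNS, "trial table")
    bad = ~df["condition"].isin(CONDITIONS)
    if bad.any():
        row = int(df.index[bad][0]) + 2  # +1 header, +1 zero-base
        raise SchemaError(
            f"trial table: malformed condition {df.loc[df.index[bad][0], 'condition']!r} "
            f"at row {row}"
        )
    bad = ~df["test_type"].isin(TEST_TYPES)
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise SchemaError(f"trial table: unknown test_type at row {row}")
    return df


def read_timeline_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TIMELINE_COLUMNS, "timeline table")
    return df


def read_results_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, RESULT_COLUMNS, "results table")
    return df


def read_neurons_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, NEURON_COLUMNS, "neuron table")
    return df


def read_audiograms_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, AUDIOGRAM_COLUMNS, "audiogram table")
    return df


def read_bdnf_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, BDNF_COLUMNS, "BDNF table")
    return df


def write_table(df: pd.DataFrame, path, *, sep: str = ",") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, lineterminator="\n")


@dataclass
class RunConfig:
    """Full pipeline configuration; ``seed`` drives every random stage."""

    seed: int | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    alpha: float = 0.05
    n_exclude: int = 4
    t_variant: str = "student"
    suppression_formula: str = "ratio_of_means"
    max_weeks: int = 12
    cf_cutoff_khz: float = 10.0
    dunn_correction: str = "bonferroni"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        kwargs = {}
        for name, sub_cls in (("sim", SimConfig), ("cohort", CohortSpec)):
            if name in raw:
                block = raw.pop(name)
                allowed = {f.name for f in fields(sub_cls)}
                unknown = set(block) - allowed
                if unknown:
                    raise SchemaError(f"unknown keys in {name!r} block: {sorted(unknown)}")
                block = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in block.items()
                }
                kwargs[name] = sub_cls(**block)
        allowed = {f.name for f in fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=list)

    def digest(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()

    def require_seed(self) -> int:
        if self.seed is None:
            raise SchemaError("a seed is required whenever simulation is requested")
        return int(self.seed)
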