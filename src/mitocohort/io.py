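"""Tabular readers/writers and the run manifest.

Report floats are printed at fixed precision (p-values to 3 significant
figures, HF to 1 decimal) so that re-runs diff cleanly; the manifest records
every threshold, family size and input digest needed to reproduce a run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .burden import SampleMeta

METADATA_COLUMNS = ["sample_id", "group", "age_death", "age_onset", "sex",
                    "region", "cjd_subtype"]
DEPTH_COLUMNS = ["sample_id", "mean_mt_depth", "mean_nuclear_depth"]


def read_metadata_tsv(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata TSV missing columns: {sorted(missing)}")
    out = []
    for row in df.to_dict("records"):
        def opt(key, cast=float):
            val = row.get(key)
            if val is None or (isinstance(val, float) and pd.isna(val)) or val == "":
                return None
            return cast(val)
        out.append(SampleMeta(
            sample_id=row["sample_id"], group=row["group"],
            age_death=opt("age_death"), age_onset=opt("age_onset"),
            sex=opt("sex", str) or "", region=opt("region", str) or "",
            cjd_subtype=opt("cjd_subtype", str),
        ))
    return out


def write_metadata_tsv(samples: list[SampleMeta], path) -> None:
    df = pd.DataFrame([{
        "sample_id": s.sample_id, "group": s.group,
        "age_death": None if s.age_death is None else round(s.age_death, 1),
        "age_onset": None if s.age_onset is None else round(s.age_onset, 1),
        "sex": s.sex, "region": s.region, "cjd_subtype": s.cjd_subtype or "",
    } for s in samples], columns=METADATA_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_depth_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(DEPTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"depth TSV missing columns: {sorted(missing)}")
    return df


def write_depth_tsv(rows: list[dict], path) -> None:
    pd.DataFrame(rows, columns=DEPTH_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.4f")


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every report bundle."""

    tool_version: str
    seed: int
    config_hash: str
    parameters: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    created_utc: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds"))

    @classmethod
    def for_run(cls, version: str, seed: int, parameters: dict,
                inputs: dict[str, str | Path] | None = None) -> "RunManifest":
        canonical = json.dumps(parameters, sort_keys=True, default=str)
        digests = {name: file_digest(p) for name, p in (inputs or {}).items()
                   if Path(p).exists()}
        return cls(tool_version=version, seed=seed,
                   config_hash=hashlib.sha256(canonical.encode()).hexdigest(),
                   parameters=parameters, input_digests=digests)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def format_p(p: float) -> str:
    """p-values at 3 significant figures, the report convention."""
    return f"{p:.3g}"
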