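"""Plain-text readers/writers: session TSVs, cohort manifests, count tables."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .de import CountMatrix
from .sessions import EVENT_COLUMNS, SessionLog


def write_session_tsv(log: SessionLog, path: str | Path) -> None:
    log.events.to_csv(path, sep="\t", index=False, columns=EVENT_COLUMNS)


def read_session_tsv(path: str | Path, schedule: str, duration_s: float,
                     meta: dict | None = None) -> SessionLog:
    events = pd.read_csv(path, sep="\t")
    events["cue_light"] = events["cue_light"].astype(bool)
    return SessionLog(schedule=schedule, duration_s=duration_s,
                      events=events, meta=meta or {})


def write_cohort(logs: dict[str, list[SessionLog]], labels: pd.DataFrame,
                 outdir: str | Path) -> Path:
    """Write one TSV per session plus a cohort manifest CSV and latent labels."""
    outdir = Path(outdir)
    sess_dir = outdir / "sessions"
    sess_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for mouse_id, mouse_logs in logs.items():
        for j, log in enumerate(mouse_logs):
            fname = f"{mouse_id}_{j:02d}_{log.schedule}.tsv"
            write_session_tsv(log, sess_dir / fname)
            rows.append({"mouse_id": mouse_id, "session_index": j,
                         "schedule": log.schedule,
                         "duration_s": log.duration_s,
                         "file": f"sessions/{fname}"})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "session_manifest.csv", index=False)
    labels.to_csv(outdir / "latent_labels.csv", index=False)
    return outdir


def read_cohort(outdir: str | Path) -> dict[str, list[SessionLog]]:
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "session_manifest.csv")
    logs: dict[str, list[SessionLog]] = {}
    for _, row in manifest.sort_values(["mouse_id", "session_index"]).iterrows():
        log = read_session_tsv(outdir / row["file"], row["schedule"],
                               row["duration_s"],
                               meta={"mouse_id": row["mouse_id"]})
        logs.setdefault(row["mouse_id"], []).append(log)
    return logs


def write_counts(cm: CountMatrix, counts_path: str | Path,
                 meta_path: str | Path) -> None:
    df = cm.counts.copy()
    df.insert(0, "feature", df.index)
    df.to_csv(counts_path, sep="\t", index=False)
    meta = pd.DataFrame({"sample_id": cm.groups.index,
                         "group": cm.groups.to_numpy()})
    meta.to_csv(meta_path, index=False)


def read_counts(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t").set_index("feature")
    df.index.name = None
    meta = pd.read_csv(meta_path)
    groups = pd.Series(meta["group"].to_numpy(), index=meta["sample_id"])
    return CountMatrix(df, groups)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
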