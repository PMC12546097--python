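"""File I/O: epochs as flat binary + JSON sidecar, tables as CSV.

EEG epochs are stored as little-endian float32 channel-major binary
(``.bin``) with a JSON sidecar (``.json``) carrying channel names,
sample rate, task label and shape — one file pair per
subject/task/trial.  Ratings and demographics go to CSV, the panel
configuration and ground truth to JSON, so a simulated panel round-trips
losslessly up to float32 quantization.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import Epoch
from .synthetic import (
    EffectSpec,
    N_TRIALS,
    PHASES,
    PanelConfig,
    SessionRecording,
    VirtualSubject,
)

_DTYPE = "<f4"  # little-endian float32


def write_epoch(epoch: Epoch, path: str | Path) -> None:
    """Write one epoch as ``<path>.bin`` + ``<path>.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(epoch.data, dtype=_DTYPE)
    path.with_suffix(".bin").write_bytes(data.tobytes())
    sidecar = {
        "channel_names": list(epoch.channel_names),
        "fs": epoch.fs,
        "n_channels": epoch.data.shape[0],
        "n_samples": epoch.data.shape[1],
        "task": epoch.task,
        "dtype": _DTYPE,
        "order": "channel-major",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_epoch(path: str | Path) -> Epoch:
    """Read an epoch written by :func:`write_epoch`.

    Raises an explicit error when the sidecar is missing or the binary
    payload does not match the sidecar's declared shape (truncation).
    """
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    raw = path.with_suffix(".bin").read_bytes()
    n_ch, n_s = sidecar["n_channels"], sidecar["n_samples"]
    expected = n_ch * n_s * np.dtype(sidecar["dtype"]).itemsize
    if len(raw) != expected:
        raise ValueError(
            f"{path.with_suffix('.bin')} holds {len(raw)} bytes, expected "
            f"{expected} ({n_ch}×{n_s} {sidecar['dtype']}): truncated or corrupt"
        )
    data = np.frombuffer(raw, dtype=sidecar["dtype"]).reshape(n_ch, n_s).astype(float)
    return Epoch(
        data=data,
        fs=sidecar["fs"],
        channel_names=list(sidecar["channel_names"]),
        task=sidecar.get("task", ""),
    )


def _config_to_dict(config: PanelConfig) -> dict:
    d = dataclasses.asdict(config)
    d["effect_map"] = {
        k: {"region": e["region"], "band": e["band"], "gain": e["gain"]}
        for k, e in d["effect_map"].items()
    }
    return d


def _config_from_dict(d: dict) -> PanelConfig:
    d = dict(d)
    d["effect_map"] = {k: EffectSpec(**v) for k, v in d["effect_map"].items()}
    for key in ("channel_names", "iaf_range", "age_range", "group_proportions",
                "latent_range", "band_limit"):
        if key in d:
            d[key] = tuple(d[key])
    return PanelConfig(**d)


def write_panel(
    subjects: list[VirtualSubject],
    sessions: list[SessionRecording],
    config: PanelConfig,
    outdir: str | Path,
) -> None:
    """Persist a simulated panel: epochs, ratings, demographics, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "panel_config.json").write_text(
        json.dumps(_config_to_dict(config), indent=2, sort_keys=True)
    )
    truth = [
        {
            "subject_id": s.subject_id,
            "age": s.age,
            "group": s.group,
            "true_iaf": s.true_iaf,
            "index": s.index,
            "latent_intensity": {
                f"{ph}|{tr}|{attr}": v
                for (ph, tr, attr), v in sorted(s.latent_intensity.items())
            },
        }
        for s in subjects
    ]
    (outdir / "subjects.json").write_text(json.dumps(truth, indent=2, sort_keys=True))

    ratings_rows = []
    for session in sessions:
        subj_dir = outdir / "epochs" / session.subject_id
        write_epoch(session.baseline, subj_dir / "BSL")
        for (phase, trial), ep in sorted(session.wr_epochs.items()):
            write_epoch(ep, subj_dir / f"{phase}_{trial}_WR")
        for (phase, trial), ep in sorted(session.tl_epochs.items()):
            write_epoch(ep, subj_dir / f"{phase}_{trial}_TL")
        for (phase, trial, attr), rating in sorted(session.ratings.items()):
            ratings_rows.append(
                {
                    "subject_id": session.subject_id,
                    "phase": phase,
                    "trial": trial,
                    "attribute": attr,
                    "rating": rating,
                }
            )
    pd.DataFrame(ratings_rows).to_csv(outdir / "ratings.csv", index=False)
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age": [s.age for s in subjects],
            "group": [s.group for s in subjects],
        }
    ).to_csv(outdir / "demographics.csv", index=False)


def read_panel(
    indir: str | Path,
) -> tuple[list[VirtualSubject], list[SessionRecording], PanelConfig]:
    """Load a panel written by :func:`write_panel`.

    Checks every epoch against the panel config (channel count and
    sample rate) and fails loudly on mismatch.
    """
    indir = Path(indir)
    config = _config_from_dict(json.loads((indir / "panel_config.json").read_text()))
    truth = json.loads((indir / "subjects.json").read_text())
    subjects = [
        VirtualSubject(
            subject_id=t["subject_id"],
            age=t["age"],
            group=t["group"],
            true_iaf=t["true_iaf"],
            index=t["index"],
            latent_intensity={
                (k.split("|")[0], int(k.split("|")[1]), k.split("|")[2]): v
                for k, v in t["latent_intensity"].items()
            },
        )
        for t in truth
    ]
    ratings = pd.read_csv(indir / "ratings.csv", float_precision="round_trip")
    sessions = []
    for subject in subjects:
        subj_dir = indir / "epochs" / subject.subject_id
        baseline = _checked(read_epoch(subj_dir / "BSL"), config, subj_dir / "BSL")
        wr, tl = {}, {}
        for phase in PHASES:
            for trial in range(1, N_TRIALS + 1):
                wr[(phase, trial)] = _checked(
                    read_epoch(subj_dir / f"{phase}_{trial}_WR"), config,
                    subj_dir / f"{phase}_{trial}_WR",
                )
                tl[(phase, trial)] = _checked(
                    read_epoch(subj_dir / f"{phase}_{trial}_TL"), config,
                    subj_dir / f"{phase}_{trial}_TL",
                )
        sub_ratings = ratings[ratings["subject_id"] == subject.subject_id]
        sessions.append(
            SessionRecording(
                subject_id=subject.subject_id,
                baseline=baseline,
                wr_epochs=wr,
                tl_epochs=tl,
                ratings={
                    (r.phase, int(r.trial), r.attribute): float(r.rating)
                    for r in sub_ratings.itertuples()
                },
            )
        )
    return subjects, sessions, config


def _checked(epoch: Epoch, config: PanelConfig, path: Path) -> Epoch:
    if epoch.data.shape[0] != config.n_channels:
        raise ValueError(
            f"{path}: {epoch.data.shape[0]} channels, manifest says {config.n_channels}"
        )
    if epoch.fs != config.fs:
        raise ValueError(f"{path}: fs={epoch.fs}, manifest says {config.fs}")
    return epoch
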