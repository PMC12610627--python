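"""Readers and writers for the pipeline's plain-text formats.

CSV dialect: UTF-8, "." decimal, header row; JSON is UTF-8. Numeric
round-trips are lossless to 1e-9 relative tolerance (values are written with
repr-level precision).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .types import (
    BehaviorCoding,
    EEGRecording,
    Event,
    EventTimeline,
    QuestionnaireResponse,
    TrustCurve,
    TrustCurvePoint,
)


def _read_csv(path: str | Path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def write_eeg_csv(recording: EEGRecording, path: str | Path) -> None:
    t = np.arange(recording.samples.size) / recording.fs
    pd.DataFrame({"time_s": t, "eeg_uV": recording.samples}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_eeg_csv(
    path: str | Path,
    *,
    rest_end_s: float = 10.0,
    participant_id: str = "",
    scenario_id: str = "",
) -> EEGRecording:
    df = _read_csv(path, {"time_s", "eeg_uV"})
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ParseError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        # +2: header line plus 1-based indexing of the second row of the pair
        raise ParseError(f"{path}: non-monotone time at line {int(bad[0]) + 3}")
    fs = 1.0 / float(np.median(dt))
    return EEGRecording(
        samples=df["eeg_uV"].to_numpy(dtype=float),
        fs=fs,
        rest_end_s=rest_end_s,
        participant_id=participant_id,
        scenario_id=scenario_id,
    )


def write_events_json(timeline: EventTimeline, path: str | Path) -> None:
    payload = [
        {"event_id": e.event_id, "t_start_s": e.t_start_s, "label": e.label, "scenario": e.scenario}
        for e in timeline.events
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_events_json(path: str | Path) -> EventTimeline:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    try:
        return EventTimeline([Event(**e) for e in payload])
    except TypeError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_questionnaire_csv(responses: list[QuestionnaireResponse], path: str | Path) -> None:
    rows = [
        {
            "participant": r.participant_id,
            "event_id": r.event_id,
            **{f"item{i:02d}": v for i, v in enumerate(r.items, start=1)},
        }
        for r in responses
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_questionnaire_csv(path: str | Path) -> list[QuestionnaireResponse]:
    cols = {"participant", "event_id"} | {f"item{i:02d}" for i in range(1, 13)}
    df = _read_csv(path, cols)
    out = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            out.append(
                QuestionnaireResponse(
                    participant_id=str(d["participant"]),
                    event_id=str(d["event_id"]),
                    items=tuple(int(d[f"item{i:02d}"]) for i in range(1, 13)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {line}: {exc}") from exc
    return out


def write_behavior_csv(codings: list[BehaviorCoding], path: str | Path) -> None:
    rows = [
        {
            "participant": c.participant_id,
            "event_id": c.event_id,
            "adherence_pct": c.adherence_pct,
            "latency_s": c.latency_s,
            "reliance": c.reliance,
            "interventions": c.interventions,
            "verifications": c.verifications,
        }
        for c in codings
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_behavior_csv(path: str | Path) -> list[BehaviorCoding]:
    cols = {"participant", "event_id", "adherence_pct", "latency_s", "reliance",
            "interventions", "verifications"}
    df = _read_csv(path, cols)
    out = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            out.append(
                BehaviorCoding(
                    participant_id=str(d["participant"]),
                    event_id=str(d["event_id"]),
                    adherence_pct=float(d["adherence_pct"]),
                    latency_s=float(d["latency_s"]),
                    reliance=int(d["reliance"]),
                    interventions=int(d["interventions"]),
                    verifications=int(d["verifications"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {line}: {exc}") from exc
    return out


def write_trust_curve_csv(
    curve: TrustCurve, path: str | Path, *, participant: str = "", scenario: str = ""
) -> None:
    rows = [
        {
            "participant": participant,
            "scenario": scenario,
            "event_id": p.event_id,
            "t_s": p.t_s,
            "modality": curve.modality,
            "score": p.score,
        }
        for p in curve.points
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_trust_curve_csv(path: str | Path) -> TrustCurve:
    df = _read_csv(path, {"participant", "scenario", "event_id", "t_s", "modality", "score"})
    if df.empty:
        raise ParseError(f"{path}: no curve points")
    modalities = df["modality"].unique()
    if len(modalities) != 1:
        raise ParseError(f"{path}: mixed modalities {sorted(modalities)}")
    points = [
        TrustCurvePoint(event_id=str(r.event_id), t_s=float(r.t_s), score=float(r.score))
        for r in df.itertuples(index=False)
    ]
    return TrustCurve(modality=str(modalities[0]), points=points)


def write_model_json(model, path: str | Path, *, training_config: dict | None = None) -> None:
    payload = model.to_dict()
    if training_config is not None:
        payload["training_config"] = training_config
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model_json(path: str | Path):
    from .anfis import AnfisModel

    try:
        return AnfisModel.from_dict(json.loads(Path(path).read_text()))
    except (json.JSONDecodeError, KeyError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_surface_csv(axis: np.ndarray, surface: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(surface, index=axis, columns=axis)
    df.index.name = "eeg\\questionnaire"
    df.to_csv(path, float_format="%.10g")
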