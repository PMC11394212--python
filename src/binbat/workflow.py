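"""End-to-end automated BAT analysis for one experiment (one donor).

Pipeline per experiment: transform every sample to the analysis scale,
pregate (singlets, debris, thrombocytes), calibrate all thresholds on the
donor's unstimulated sample, apply the frozen threshold set to every
sample, compute activation readouts, attach quality-control flags, and
derive the responder status and per-allergen activation calls.

The activation-call cutoffs (responder: positive-control CD63+% at or
above 10%; allergen positive: CD63+% at or above 5% AND at least twice
the unstimulated baseline) are auditable package defaults — every call
carries the rule string that produced it — and are config-exposed.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .calibration import (
    CalibrationConfig,
    ThresholdSet,
    apply_thresholds,
    calibrate,
)
from .errors import CalibrationError, ConfigError, InsufficientEventsError
from .events import Condition, EventTable, SampleMeta
from .pregate import PregateConfig, pregate
from .transform import TransformSpec, apply_transform


class QCCode(str, enum.Enum):
    LOW_EVENTS = "LOW_EVENTS"
    LOW_BASOPHILS = "LOW_BASOPHILS"
    THRESHOLD_OUT_OF_RANGE = "THRESHOLD_OUT_OF_RANGE"
    CALIBRATION_FAILED = "CALIBRATION_FAILED"
    EMPTY_QUADRANT = "EMPTY_QUADRANT"
    DEGENERATE_Z = "DEGENERATE_Z"


class Severity(str, enum.Enum):
    WARNING = "WARNING"
    BLOCKING = "BLOCKING"


@dataclass(frozen=True)
class QCFlag:
    code: QCCode
    severity: Severity
    message: str

    def to_dict(self) -> dict:
        return {"code": self.code.value, "severity": self.severity.value,
                "message": self.message}

    @classmethod
    def from_dict(cls, d) -> "QCFlag":
        return cls(QCCode(d["code"]), Severity(d["severity"]), d["message"])


class ResponderStatus(str, enum.Enum):
    RESPONDER = "RESPONDER"
    NON_RESPONDER = "NON_RESPONDER"
    UNDETERMINED = "UNDETERMINED"


class AllergenCall(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class WorkflowConfig:
    responder_cutoff: float = 10.0  # % CD63+ in the positive control
    activation_cutoff: float = 5.0  # % CD63+ for a positive allergen call
    activation_fold: float = 2.0    # and at least this multiple of baseline
    qc_min_events: int = 5000
    qc_min_basophils_warn: int = 50
    qc_min_basophils_block: int = 10
    qc_threshold_span: tuple[float, float] = (0.0, 100.0)  # percentile span
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    pregate: PregateConfig = field(default_factory=PregateConfig)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class SampleResult:
    meta: SampleMeta
    n_gated: int
    n_basophils: int
    cd63_pos_pct: float | None
    cd32_pos_pct: float | None
    thresholds: ThresholdSet | None
    qc_flags: list[QCFlag] = field(default_factory=list)

    @property
    def blocked(self) -> bool:
        return any(f.severity is Severity.BLOCKING for f in self.qc_flags)

    def to_dict(self) -> dict:
        return {
            "meta": self.meta.to_dict(),
            "n_gated": self.n_gated,
            "n_basophils": self.n_basophils,
            "cd63_pos_pct": self.cd63_pos_pct,
            "cd32_pos_pct": self.cd32_pos_pct,
            "thresholds": self.thresholds.to_dict() if self.thresholds else None,
            "qc_flags": [f.to_dict() for f in self.qc_flags],
        }

    @classmethod
    def from_dict(cls, d) -> "SampleResult":
        return cls(
            meta=SampleMeta.from_dict(d["meta"]),
            n_gated=d["n_gated"],
            n_basophils=d["n_basophils"],
            cd63_pos_pct=d["cd63_pos_pct"],
            cd32_pos_pct=d["cd32_pos_pct"],
            thresholds=ThresholdSet.from_dict(d["thresholds"]) if d["thresholds"] else None,
            qc_flags=[QCFlag.from_dict(f) for f in d["qc_flags"]],
        )


@dataclass
class ExperimentResult:
    donor_id: str
    samples: list[SampleResult]
    responder_status: ResponderStatus
    allergen_calls: dict[str, AllergenCall]
    call_rules: dict[str, str] = field(default_factory=dict)
    thresholds: ThresholdSet | None = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "donor_id": self.donor_id,
            "samples": [s.to_dict() for s in self.samples],
            "responder_status": self.responder_status.value,
            "allergen_calls": {k: v.value for k, v in self.allergen_calls.items()},
            "call_rules": dict(self.call_rules),
            "thresholds": self.thresholds.to_dict() if self.thresholds else None,
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d) -> "ExperimentResult":
        return cls(
            donor_id=d["donor_id"],
            samples=[SampleResult.from_dict(s) for s in d["samples"]],
            responder_status=ResponderStatus(d["responder_status"]),
            allergen_calls={k: AllergenCall(v) for k, v in d["allergen_calls"].items()},
            call_rules=dict(d.get("call_rules", {})),
            thresholds=ThresholdSet.from_dict(d["thresholds"]) if d.get("thresholds") else None,
            config=d.get("config", {}),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def responder_status_from(
    pos_ctrl_cd63_pct: float | None,
    blocked: bool,
    cfg: WorkflowConfig = WorkflowConfig(),
) -> ResponderStatus:
    """Pure responder rule: positive-control CD63+% against the cutoff."""
    if blocked or pos_ctrl_cd63_pct is None:
        return ResponderStatus.UNDETERMINED
    if pos_ctrl_cd63_pct >= cfg.responder_cutoff:
        return ResponderStatus.RESPONDER
    return ResponderStatus.NON_RESPONDER


def allergen_call_from(
    allergen_cd63_pct: float | None,
    unstim_cd63_pct: float | None,
    status: ResponderStatus,
    blocked: bool,
    cfg: WorkflowConfig = WorkflowConfig(),
) -> AllergenCall:
    """Pure allergen rule: absolute cutoff AND fold over baseline; any
    non-responder or blocked input forces UNDETERMINED."""
    if (status is not ResponderStatus.RESPONDER or blocked
            or allergen_cd63_pct is None or unstim_cd63_pct is None):
        return AllergenCall.UNDETERMINED
    if (allergen_cd63_pct >= cfg.activation_cutoff
            and allergen_cd63_pct >= cfg.activation_fold * unstim_cd63_pct):
        return AllergenCall.POSITIVE
    return AllergenCall.NEGATIVE


def evaluate_qc(
    sr: SampleResult,
    cfg: WorkflowConfig = WorkflowConfig(),
    channel_spans: Mapping[str, tuple[float, float]] | None = None,
) -> list[QCFlag]:
    """Pure QC rule evaluation for one sample result.

    ``channel_spans`` maps marker names to the observed (low, high)
    percentile span used for the out-of-range check; without it that
    check is skipped.
    """
    flags: list[QCFlag] = []
    if sr.n_gated < cfg.qc_min_events:
        flags.append(QCFlag(QCCode.LOW_EVENTS, Severity.WARNING,
                            f"only {sr.n_gated} gated events (< {cfg.qc_min_events})"))
    if sr.n_basophils < cfg.qc_min_basophils_block:
        flags.append(QCFlag(QCCode.LOW_BASOPHILS, Severity.BLOCKING,
                            f"only {sr.n_basophils} basophil events "
                            f"(< {cfg.qc_min_basophils_block})"))
    elif sr.n_basophils < cfg.qc_min_basophils_warn:
        flags.append(QCFlag(QCCode.LOW_BASOPHILS, Severity.WARNING,
                            f"only {sr.n_basophils} basophil events "
                            f"(< {cfg.qc_min_basophils_warn})"))
    if sr.n_basophils == 0:
        flags.append(QCFlag(QCCode.EMPTY_QUADRANT, Severity.BLOCKING,
                            "basophil quadrant is empty"))
    if sr.thresholds is not None and channel_spans is not None:
        per_marker = {
            "SSC": sr.thresholds.thr_ssc,
            "FCER1A": sr.thresholds.thr_fcer1a,
            "CD63": sr.thresholds.thr_cd63,
            "CD32": sr.thresholds.thr_cd32,
        }
        for marker, thr in per_marker.items():
            if marker not in channel_spans:
                continue
            lo, hi = channel_spans[marker]
            if not (lo <= thr <= hi):
                flags.append(QCFlag(
                    QCCode.THRESHOLD_OUT_OF_RANGE, Severity.WARNING,
                    f"{marker} threshold {thr:.4g} outside observed "
                    f"[{lo:.4g}, {hi:.4g}] span",
                ))
    return flags


def _channel_spans(table: EventTable, cfg: WorkflowConfig) -> dict[str, tuple[float, float]]:
    lo_q, hi_q = cfg.qc_threshold_span
    spans = {}
    for marker in ("SSC", "FCER1A", "CD63", "CD32"):
        v = table.marker_values(marker)
        spans[marker] = (float(np.percentile(v, lo_q)), float(np.percentile(v, hi_q)))
    return spans


def prepare_sample(table: EventTable, cfg: WorkflowConfig,
                   spec: TransformSpec | None = None) -> EventTable:
    """Transform (if not already on the analysis scale) and pregate."""
    if not table.marker_transformed("FCER1A"):
        spec = spec or TransformSpec.default_for(table)
        table = apply_transform(table, spec)
    return pregate(table, cfg.pregate)


def analyze_experiment(
    samples: Sequence[tuple[EventTable, SampleMeta]],
    cfg: WorkflowConfig = WorkflowConfig(),
) -> ExperimentResult:
    """Run the full automated workflow on one donor's samples."""
    metas = [m for _, m in samples]
    unstim_idx = [i for i, m in enumerate(metas) if m.condition is Condition.UNSTIM]
    if len(unstim_idx) != 1:
        raise ConfigError(
            f"experiment needs exactly one UNSTIM sample, got {len(unstim_idx)}"
        )
    if len(samples) < 2:
        raise ConfigError("experiment needs at least one non-UNSTIM sample")
    donors = {m.donor_id for m in metas}
    if len(donors) != 1:
        raise ConfigError(f"experiment mixes donors: {sorted(donors)}")
    donor_id = metas[0].donor_id

    gated = [(prepare_sample(t, cfg), m) for t, m in samples]
    unstim_table, unstim_meta = gated[unstim_idx[0]]

    rule_strings = {
        "responder": f"POS_CTRL CD63+% >= {cfg.responder_cutoff}",
        "allergen": (f"CD63+% >= {cfg.activation_cutoff} and >= "
                     f"{cfg.activation_fold} x UNSTIM CD63+%"),
    }

    try:
        thresholds, cal_warnings = calibrate(
            unstim_table, unstim_meta.sample_id, cfg.calibration
        )
    except (CalibrationError, InsufficientEventsError) as exc:
        flag = QCFlag(QCCode.CALIBRATION_FAILED, Severity.BLOCKING, str(exc))
        results = [
            SampleResult(meta=m, n_gated=t.n_events, n_basophils=0,
                         cd63_pos_pct=None, cd32_pos_pct=None,
                         thresholds=None, qc_flags=[flag])
            for t, m in gated
        ]
        calls = {m.allergen_name: AllergenCall.UNDETERMINED
                 for m in metas if m.condition is Condition.ALLERGEN}
        return ExperimentResult(
            donor_id=donor_id, samples=results,
            responder_status=ResponderStatus.UNDETERMINED,
            allergen_calls=calls, call_rules=rule_strings,
            thresholds=None, config=cfg.to_dict(),
        )

    results: list[SampleResult] = []
    for table, meta in gated:
        app = apply_thresholds(table, thresholds, cfg.calibration.bin_width)
        sr = SampleResult(
            meta=meta, n_gated=app.n_gated, n_basophils=app.n_basophils,
            cd63_pos_pct=app.cd63_pos_pct, cd32_pos_pct=app.cd32_pos_pct,
            thresholds=thresholds,
        )
        sr.qc_flags = evaluate_qc(sr, cfg, _channel_spans(table, cfg))
        if meta.condition is Condition.UNSTIM:
            for w in cal_warnings:
                code = QCCode.DEGENERATE_Z if "degenerate" in w else QCCode.LOW_BASOPHILS
                if not any(f.message == w for f in sr.qc_flags):
                    sr.qc_flags.append(QCFlag(code, Severity.WARNING, w))
        results.append(sr)

    by_cond = {m.condition: r for r, m in zip(results, metas)}
    unstim_r = by_cond[Condition.UNSTIM]
    pos_r = by_cond.get(Condition.POS_CTRL)

    if pos_r is None:
        status = ResponderStatus.UNDETERMINED
    else:
        status = responder_status_from(pos_r.cd63_pos_pct, pos_r.blocked, cfg)

    calls: dict[str, AllergenCall] = {}
    for sr, meta in zip(results, metas):
        if meta.condition is not Condition.ALLERGEN:
            continue
        name = meta.allergen_name or "allergen"
        calls[name] = allergen_call_from(
            sr.cd63_pos_pct, unstim_r.cd63_pos_pct, status,
            sr.blocked or unstim_r.blocked, cfg,
        )

    return ExperimentResult(
        donor_id=donor_id, samples=results, responder_status=status,
        allergen_calls=calls, call_rules=rule_strings,
        thresholds=thresholds, config=cfg.to_dict(),
    )


# ---------------------------------------------------------------------------
# result persistence: per-experiment JSON + tabular CSV + append-only index


def write_results(result: ExperimentResult, out_dir: str | Path) -> dict[str, Path]:
    """Write one experiment's results: a JSON document, a per-sample CSV
    and an append-only experiment index row.  Round-trip safe."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / f"{result.donor_id}_result.json"
    csv_path = out_dir / f"{result.donor_id}_samples.csv"
    json_path.write_text(result.to_json())

    fieldnames = ["donor_id", "condition", "allergen_name", "n_gated", "n_basophils",
                  "cd63_pos_pct", "cd32_pos_pct", "qc_flags"]
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for s in result.samples:
            writer.writerow({
                "donor_id": s.meta.donor_id,
                "condition": s.meta.condition.value,
                "allergen_name": s.meta.allergen_name or "",
                "n_gated": s.n_gated,
                "n_basophils": s.n_basophils,
                "cd63_pos_pct": "" if s.cd63_pos_pct is None else repr(s.cd63_pos_pct),
                "cd32_pos_pct": "" if s.cd32_pos_pct is None else repr(s.cd32_pos_pct),
                "qc_flags": ";".join(f"{f.code.value}:{f.severity.value}" for f in s.qc_flags),
            })

    index_path = out_dir / "experiment_index.csv"
    new = not index_path.exists()
    with open(index_path, "a", newline="") as fh:
        writer = csv.writer(fh)
        if new:
            writer.writerow(["donor_id", "n_samples", "responder_status", "result_json"])
        writer.writerow([result.donor_id, len(result.samples),
                         result.responder_status.value, json_path.name])
    return {"json": json_path, "csv": csv_path, "index": index_path}


def read_results(json_path: str | Path) -> ExperimentResult:
    return ExperimentResult.from_dict(json.loads(Path(json_path).read_text()))
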