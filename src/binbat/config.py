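"""Run configuration: one YAML/JSON document drives the whole pipeline.

Sections: ``channel_map`` (logical marker -> channel), ``transform``
(per-channel method + cofactor; derived from the channel map when
omitted), ``pregate``, ``calibration`` and ``workflow`` cutoffs, plus the
master ``seed``.  A run's config (and its hash) is embedded in every
result document for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import CalibrationConfig
from .errors import ConfigError
from .events import ChannelMap, EventTable
from .pregate import PregateConfig
from .transform import ChannelTransform, Method, TransformSpec
from .workflow import WorkflowConfig


@dataclass(frozen=True)
class RunConfig:
    channel_map: ChannelMap
    transform: TransformSpec | None = None  # None: derive defaults per table
    workflow: WorkflowConfig = field(default_factory=WorkflowConfig)
    seed: int = 0

    def transform_for(self, table: EventTable) -> TransformSpec:
        return self.transform if self.transform is not None else TransformSpec.default_for(table)

    def to_dict(self) -> dict:
        d: dict = {
            "channel_map": dict(self.channel_map.mapping),
            "seed": self.seed,
            "workflow": {
                "responder_cutoff": self.workflow.responder_cutoff,
                "activation_cutoff": self.workflow.activation_cutoff,
                "activation_fold": self.workflow.activation_fold,
                "qc_min_events": self.workflow.qc_min_events,
                "qc_min_basophils_warn": self.workflow.qc_min_basophils_warn,
                "qc_min_basophils_block": self.workflow.qc_min_basophils_block,
                "qc_threshold_span": list(self.workflow.qc_threshold_span),
            },
            "calibration": {
                "cd63_target_pct": self.workflow.calibration.cd63_target_pct,
                "cd32_target_pct": self.workflow.calibration.cd32_target_pct,
                "cd32_purity_min": self.workflow.calibration.cd32_purity_min,
                "baso_freq_bounds": list(self.workflow.calibration.baso_freq_bounds),
                "fcer1a_quantile_grid": list(self.workflow.calibration.fcer1a_quantile_grid),
                "ssc_quantile_grid": list(self.workflow.calibration.ssc_quantile_grid),
                "cd32_provisional_quantile": self.workflow.calibration.cd32_provisional_quantile,
                "bin_width": self.workflow.calibration.bin_width,
            },
            "pregate": {
                "singlet_band_k": self.workflow.pregate.singlet_band_k,
                "fsc_debris_min": self.workflow.pregate.fsc_debris_min,
                "fsc_thrombocyte_min": self.workflow.pregate.fsc_thrombocyte_min,
                "eosinophil_exclusion": self.workflow.pregate.eosinophil_exclusion,
                "seed": self.workflow.pregate.seed,
            },
        }
        if self.transform is not None:
            d["transform"] = {
                ch: {"method": tf.method.value, "cofactor": tf.cofactor}
                for ch, tf in self.transform.channels.items()
            }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            cmap = ChannelMap(d["channel_map"])
        except KeyError:
            raise ConfigError("config.channel_map is required") from None
        except ValueError as exc:
            raise ConfigError(f"config.channel_map: {exc}") from exc
        transform = None
        if "transform" in d:
            try:
                transform = TransformSpec({
                    ch: ChannelTransform(Method(tf.get("method", "ASINH")),
                                         float(tf.get("cofactor", 150.0)))
                    for ch, tf in d["transform"].items()
                })
            except (ValueError, AttributeError) as exc:
                raise ConfigError(f"config.transform: {exc}") from exc

        def build(section: str, cls_, **extra):
            try:
                return cls_(**{**d.get(section, {}), **extra})
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"config.{section}: {exc}") from exc

        cal_kwargs = dict(d.get("calibration", {}))
        for key in ("baso_freq_bounds", "fcer1a_quantile_grid", "ssc_quantile_grid"):
            if key in cal_kwargs:
                cal_kwargs[key] = tuple(cal_kwargs[key])
        try:
            calibration = CalibrationConfig(**cal_kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"config.calibration: {exc}") from exc
        pregate = build("pregate", PregateConfig)
        wf_kwargs = dict(d.get("workflow", {}))
        if "qc_threshold_span" in wf_kwargs:
            wf_kwargs["qc_threshold_span"] = tuple(wf_kwargs["qc_threshold_span"])
        try:
            workflow = WorkflowConfig(calibration=calibration, pregate=pregate, **wf_kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"config.workflow: {exc}") from exc
        return cls(channel_map=cmap, transform=transform, workflow=workflow,
                   seed=int(d.get("seed", 0)))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
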