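"""Synthetic whole-blood BAT cytometry generator with retained ground truth.

Emulates the statistical structure the analysis assumes: a rare basophil
population (about 0.5% of events; side-scatter-low, FcεRIα-high, CD32+,
CD123+, HLA-DR-negative) among distractor populations (lymphocytes,
monocytes, dendritic cells, neutrophils, debris, thrombocytes, doublets);
a condition-dependent CD63+ activation fraction; a positive FcεRIα-CD32
correlation within basophils; a CD32 down-shift on activated (CD63+)
basophils, which produces the CD63-CD32 anticorrelation; and a lower
basophil CD32 baseline for allergic donors.

Marker components are Gaussian on the asinh-transformed scale (i.e.
log-normal-like raw intensities) and are inverted to raw instrument units
before emission, so the pipeline's own transform step is exercised.
Forward scatter is linear; doublets are synthesised by merging two events
(FSC-A summed, FSC-H the maximum, fluorescence and side-scatter summed on
the raw scale).  Every event carries a ground-truth population label and
an activation flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import ChannelMap, Condition, EventTable, SampleMeta
from .transform import DEFAULT_FLUOR_COFACTOR, DEFAULT_SSC_COFACTOR

#: Physical channel names emitted by the generator.
CHANNELS = ("FSC-A", "FSC-H", "SSC-A", "FceR1a-PE-Vio770", "CD63-VioBlue",
            "CD32-AF647", "CD123-FITC", "HLA-DR-PerCP")

#: Logical marker -> generator channel.
CHANNEL_MAP = ChannelMap({
    "FSC_A": "FSC-A", "FSC_H": "FSC-H", "SSC": "SSC-A",
    "FCER1A": "FceR1a-PE-Vio770", "CD63": "CD63-VioBlue",
    "CD32": "CD32-AF647", "CD123": "CD123-FITC", "HLA_DR": "HLA-DR-PerCP",
})

_FLUOR = ("FCER1A", "CD63", "CD32", "CD123", "HLA_DR")

#: Per-population (mean, sd): FSC_A in linear units, the rest on the
#: asinh-transformed scale.  CD63 entries are the resting component; the
#: activated CD63 component for basophils is separate (see profile).
_POPS: dict[str, dict[str, tuple[float, float]]] = {
    "basophil": {"FSC_A": (50_000, 6_000), "SSC": (2.2, 0.25), "FCER1A": (4.5, 0.35),
                 "CD32": (4.4, 0.30), "CD63": (0.8, 0.40), "CD123": (4.0, 0.30),
                 "HLA_DR": (0.5, 0.30)},
    "lymphocyte": {"FSC_A": (45_000, 6_000), "SSC": (2.6, 0.30), "FCER1A": (0.6, 0.40),
                   "CD32": (1.0, 0.50), "CD63": (0.5, 0.30), "CD123": (0.5, 0.30),
                   "HLA_DR": (2.5, 1.00)},
    "monocyte": {"FSC_A": (70_000, 8_000), "SSC": (3.6, 0.25), "FCER1A": (1.5, 0.50),
                 "CD32": (4.2, 0.30), "CD63": (1.0, 0.40), "CD123": (1.5, 0.40),
                 "HLA_DR": (4.5, 0.40)},
    "dc": {"FSC_A": (65_000, 8_000), "SSC": (3.2, 0.25), "FCER1A": (2.6, 0.35),
           "CD32": (2.5, 0.50), "CD63": (0.8, 0.30), "CD123": (4.2, 0.40),
           "HLA_DR": (4.5, 0.40)},
    "neutrophil": {"FSC_A": (65_000, 8_000), "SSC": (4.6, 0.30), "FCER1A": (0.8, 0.40),
                   "CD32": (3.0, 0.40), "CD63": (0.8, 0.40), "CD123": (0.8, 0.30),
                   "HLA_DR": (0.5, 0.30)},
    "debris": {"FSC_A": (5_000, 1_500), "SSC": (1.0, 0.50), "FCER1A": (0.3, 0.30),
               "CD32": (0.3, 0.30), "CD63": (0.3, 0.30), "CD123": (0.3, 0.30),
               "HLA_DR": (0.3, 0.30)},
    "thrombocyte": {"FSC_A": (12_000, 3_000), "SSC": (1.2, 0.40), "FCER1A": (0.3, 0.30),
                    "CD32": (0.5, 0.30), "CD63": (2.0, 0.50), "CD123": (0.3, 0.30),
                    "HLA_DR": (0.3, 0.30)},
}

_DEFAULT_FRACTIONS = {
    "basophil": 0.005, "lymphocyte": 0.28, "monocyte": 0.08, "dc": 0.01,
    "neutrophil": 0.555, "debris": 0.04, "thrombocyte": 0.03,
}


@dataclass(frozen=True)
class SyntheticProfile:
    """Generative parameters for one donor."""

    allergic: bool = False
    responder: bool = True
    pop_fractions: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_FRACTIONS))
    marker_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {p: dict(m) for p, m in _POPS.items()}
    )
    #: Per-condition activated-basophil fraction.
    p_act: dict[Condition, float] = field(default_factory=dict)
    doublet_rate: float = 0.02
    rho_fcer1a_cd32: float = 0.6
    cd63_activated: tuple[float, float] = (5.5, 0.4)  # >= 4 scale units above resting
    cd32_activation_shift: float = 0.4
    cd32_allergic_shift: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.pop_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pop_fractions must sum to 1 (got {total})")
        if not all(s > 0 for m in self.marker_params.values() for _, s in m.values()):
            raise ValueError("marker scales must be > 0")
        if not 0 <= self.doublet_rate < 0.5:
            raise ValueError("doublet_rate must be in [0, 0.5)")
        defaults = {
            Condition.UNSTIM: 0.01,
            Condition.POS_CTRL: 0.40 if self.responder else 0.02,
            Condition.ALLERGEN: 0.30 if (self.allergic and self.responder) else 0.01,
        }
        merged = {**defaults, **{Condition(k): v for k, v in self.p_act.items()}}
        if not all(0.0 <= v <= 1.0 for v in merged.values()):
            raise ValueError("activation fractions must lie in [0, 1]")
        object.__setattr__(self, "p_act", merged)

    def with_activation(self, condition: Condition, p: float) -> "SyntheticProfile":
        return replace(self, p_act={**self.p_act, Condition(condition): p})

    def without_basophils(self) -> "SyntheticProfile":
        """Ablation: redistribute the basophil mass to lymphocytes."""
        fr = dict(self.pop_fractions)
        fr["lymphocyte"] = fr.get("lymphocyte", 0.0) + fr.pop("basophil", 0.0)
        fr["basophil"] = 0.0
        return replace(self, pop_fractions=fr)


def _to_raw(marker: str, transformed: np.ndarray) -> np.ndarray:
    cofactor = DEFAULT_SSC_COFACTOR if marker == "SSC" else DEFAULT_FLUOR_COFACTOR
    return np.sinh(transformed) * cofactor


def generate_sample(
    profile: SyntheticProfile,
    condition: Condition,
    n_events: int,
    seed: int | np.random.SeedSequence,
) -> tuple[EventTable, pd.DataFrame]:
    """Draw one sample; returns the raw-scale event table and per-event
    ground truth (``population``, ``activated``)."""
    if n_events < 1000:
        raise ValueError("n_events must be >= 1000")
    condition = Condition(condition)
    rng = np.random.default_rng(seed)

    n_doublets = int(round(profile.doublet_rate * n_events))
    n_singles = n_events - n_doublets
    pops = list(profile.pop_fractions)
    probs = np.array([profile.pop_fractions[p] for p in pops])
    # singlet pool plus two parents per doublet
    n_pool = n_singles + 2 * n_doublets
    labels = rng.choice(len(pops), size=n_pool, p=probs)

    trans = {m: np.empty(n_pool) for m in ("SSC",) + _FLUOR}
    fsc_a = np.empty(n_pool)
    activated = np.zeros(n_pool, dtype=bool)
    p_act = profile.p_act[condition]

    for pi, pop in enumerate(pops):
        idx = np.flatnonzero(labels == pi)
        if idx.size == 0:
            continue
        params = profile.marker_params[pop]
        mu, sd = params["FSC_A"]
        fsc_a[idx] = np.clip(rng.normal(mu, sd, idx.size), 1.0, None)
        if pop == "basophil":
            # shared-latent bivariate normal for (FcεRIα, CD32)
            rho = profile.rho_fcer1a_cd32
            z0 = rng.standard_normal(idx.size)
            z1 = rng.standard_normal(idx.size)
            m_fc, s_fc = params["FCER1A"]
            m_32, s_32 = params["CD32"]
            if profile.allergic:
                m_32 -= profile.cd32_allergic_shift
            trans["FCER1A"][idx] = m_fc + s_fc * z0
            trans["CD32"][idx] = m_32 + s_32 * (rho * z0 + np.sqrt(1 - rho**2) * z1)
            act = rng.random(idx.size) < p_act
            activated[idx] = act
            m_63, s_63 = params["CD63"]
            cd63 = m_63 + s_63 * rng.standard_normal(idx.size)
            m_act, s_act = profile.cd63_activated
            cd63[act] = m_act + s_act * rng.standard_normal(int(act.sum()))
            trans["CD63"][idx] = cd63
            trans["CD32"][idx[act]] -= profile.cd32_activation_shift
            for m in ("SSC", "CD123", "HLA_DR"):
                mu, sd = params[m]
                trans[m][idx] = rng.normal(mu, sd, idx.size)
        else:
            for m in ("SSC",) + _FLUOR:
                mu, sd = params[m]
                trans[m][idx] = rng.normal(mu, sd, idx.size)

    raw = {m: _to_raw(m, trans[m]) for m in ("SSC",) + _FLUOR}
    fsc_h = np.clip(fsc_a * 0.95 + rng.normal(0.0, 0.02 * fsc_a), 1.0, None)

    # assemble singles, then merge doublet parents pairwise
    cols = {
        "FSC_A": fsc_a, "FSC_H": fsc_h, "SSC": raw["SSC"],
        **{m: raw[m] for m in _FLUOR},
    }
    single = {m: v[:n_singles] for m, v in cols.items()}
    pa = {m: v[n_singles : n_singles + n_doublets] for m, v in cols.items()}
    pb = {m: v[n_singles + n_doublets :] for m, v in cols.items()}
    merged = {m: pa[m] + pb[m] for m in cols}
    merged["FSC_H"] = np.maximum(pa["FSC_H"], pb["FSC_H"])

    order = ("FSC_A", "FSC_H", "SSC") + _FLUOR
    values = np.vstack([
        np.column_stack([single[m] for m in order]),
        np.column_stack([merged[m] for m in order]),
    ])
    pop_labels = np.concatenate([
        np.array(pops, dtype=object)[labels[:n_singles]],
        np.full(n_doublets, "doublet", dtype=object),
    ])
    act_labels = np.concatenate([activated[:n_singles], np.zeros(n_doublets, dtype=bool)])

    # shuffle so event order carries no population structure
    perm = rng.permutation(n_events)
    values = values[perm]
    truth = pd.DataFrame({"population": pop_labels[perm], "activated": act_labels[perm]})

    table = EventTable(
        values=values,
        channel_names=CHANNELS,
        channel_map=CHANNEL_MAP,
        metadata={"condition": condition.value, "p_act": p_act, "synthetic": True},
    )
    return table, truth


def generate_experiment(
    profile: SyntheticProfile,
    conditions: tuple[Condition, ...] = (Condition.UNSTIM, Condition.POS_CTRL, Condition.ALLERGEN),
    n_events: int = 50_000,
    seed: int = 0,
    donor_id: str = "D0",
    allergen_name: str = "allergen",
) -> list[tuple[EventTable, SampleMeta, pd.DataFrame]]:
    """One sample per condition from a shared donor profile, with
    per-sample seeds derived deterministically from the master seed."""
    conditions = tuple(Condition(c) for c in conditions)
    if Condition.UNSTIM not in conditions:
        raise ValueError("conditions must include UNSTIM")
    children = np.random.SeedSequence(seed).spawn(len(conditions))
    out = []
    for cond, child in zip(conditions, children):
        table, truth = generate_sample(profile, cond, n_events, child)
        meta = SampleMeta(
            donor_id=donor_id, condition=cond,
            allergen_name=allergen_name if cond is Condition.ALLERGEN else None,
        )
        out.append((table, meta, truth))
    return out


def generate_cohort(
    n_experiments: int,
    base_profile: SyntheticProfile = SyntheticProfile(),
    seed: int = 0,
    conditions: tuple[Condition, ...] = (Condition.UNSTIM,),
    n_events: int = 20_000,
) -> list[dict]:
    """Paired cohort: each experiment holds one allergic and one
    non-allergic donor whose profiles differ by the CD32 baseline shift."""
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    children = np.random.SeedSequence(seed).spawn(2 * n_experiments)
    cohort = []
    for i in range(n_experiments):
        entry = {"experiment": f"E{i:03d}"}
        for j, allergic in enumerate((False, True)):
            profile = replace(base_profile, allergic=allergic)
            donor = f"E{i:03d}_{'A' if allergic else 'N'}"
            child_seed = int(children[2 * i + j].generate_state(1)[0] % (2**31))
            entry["allergic" if allergic else "non_allergic"] = generate_experiment(
                profile, conditions, n_events, seed=child_seed, donor_id=donor,
            )
        cohort.append(entry)
    return cohort
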