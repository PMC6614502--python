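"""Synthetic LC-MS batches with planted ground truth.

The generator emulates the batch design this package analyses: a leading
block of conditioning QCs, then repeated deconditioning/conditioning cycles
-- three consecutive extraction blanks ("intense" deconditioning) or a
single blank ("mild") followed by eight replicate sample injections.  Every
feature is planted in one of seven classes:

* ``informative_stable``   -- real analyte, unaffected by blanks;
* ``informative_cluster1`` -- real analyte with a small immediate post-blank
  deviation that decays to baseline within a few injections;
* ``informative_cluster2`` -- late-eluting lipophilic analyte whose response
  rises to a maximum a few injections after the blank and recovers at the
  planted recovery position k (these also shift in RT and peak width);
* ``contaminant``          -- background signal present in samples and
  blanks alike (plasticizers, solvent impurities);
* ``carryover_1/2/3``      -- column carry-over eluting over the first
  1/2/3 blanks and reappearing in samples from position k+1 onward.

Intensities are baseline x smooth multiplicative drift x deconditioning
response x multiplicative log-normal noise.  Informative features carry
zero area in blanks (extraction blanks contain no matrix), so the
blank-ratio clean-up condition holds for them by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .io import PeakTable, annotate_sequence

__all__ = [
    "DeconditionParams",
    "SimulationConfig",
    "SyntheticTruth",
    "decondition_response",
    "generate_batch",
    "plasma_like",
    "urine_like",
]

FEATURE_CLASSES = (
    "informative_stable",
    "informative_cluster1",
    "informative_cluster2",
    "contaminant",
    "carryover_1",
    "carryover_2",
    "carryover_3",
)

INFORMATIVE_CLASSES = FEATURE_CLASSES[:3]

#: retention-time windows per class (min); cluster-2 analytes are the
#: late-eluting lipophilic fraction, carry-over elutes late as well
RT_WINDOWS = {
    "informative_stable": (0.5, 6.0),
    "informative_cluster1": (0.5, 4.4),
    "informative_cluster2": (4.6, 6.0),
    "contaminant": (0.2, 6.5),
    "carryover_1": (3.8, 6.0),
    "carryover_2": (3.8, 6.0),
    "carryover_3": (3.8, 6.0),
}


@dataclass
class DeconditionParams:
    """Piecewise-linear post-blank response: 1 -> 1+max_dev at p_max -> 1 at k."""

    p_max: int
    k: int
    max_dev: float

    def __post_init__(self):
        if not 1 <= self.p_max <= 8:
            raise ValueError("p_max must be in 1..8")
        if not self.p_max <= self.k <= 8:
            raise ValueError("recovery position k must be in p_max..8")


@dataclass
class SimulationConfig:
    """Batch-design and noise parameters of the synthetic generator.

    Defaults mirror the plasma-style study conditions at desk scale:
    10 leading QCs, 8 intense and 8 mild cycles, ~15% smooth drift,
    5% instrumental RSD, cluster-2 response peaking at position 3 and
    recovering at position 6, and a 0.04 min post-blank RT shift.
    """

    n_features_by_class: dict = field(
        default_factory=lambda: {
            "informative_stable": 10,
            "informative_cluster1": 75,
            "informative_cluster2": 65,
            "contaminant": 80,
            "carryover_1": 10,
            "carryover_2": 5,
            "carryover_3": 15,
        }
    )
    n_cycles_intense: int = 8
    n_cycles_mild: int = 8
    n_leading_qc: int = 10
    drift_amplitude: float = 0.15
    noise_rsd: float = 0.05
    decondition_params: dict = field(
        default_factory=lambda: {
            1: DeconditionParams(p_max=1, k=4, max_dev=0.10),
            2: DeconditionParams(p_max=3, k=6, max_dev=0.50),
        }
    )
    mild_attenuation: float = 0.5
    rt_shift_minutes: float = 0.04
    rt_noise_minutes: float = 0.005
    width_shift_frac: float = 0.15
    width_noise_frac: float = 0.02
    carryover_blank_decay: float = 0.5
    baseline_decades: tuple = (4.0, 8.0)  # log10 intensity range
    seed: int = 0

    def __post_init__(self):
        counts = self.n_features_by_class
        bad = set(counts) - set(FEATURE_CLASSES)
        if bad:
            raise ValueError(f"unknown feature classes {sorted(bad)}")
        if any(v < 0 for v in counts.values()):
            raise ValueError("feature counts must be >= 0")
        if not 0 <= self.drift_amplitude < 1:
            raise ValueError("drift_amplitude must be in [0, 1)")
        if self.noise_rsd < 0:
            raise ValueError("noise_rsd must be >= 0")
        params = dict(self.decondition_params)
        for c, p in params.items():
            if not isinstance(p, DeconditionParams):
                params[c] = DeconditionParams(*p)
        self.decondition_params = params

    @property
    def n_informative(self) -> int:
        return sum(self.n_features_by_class.get(c, 0) for c in INFORMATIVE_CLASSES)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "decondition_params" in d:
            d["decondition_params"] = {
                int(c): DeconditionParams(**p) if isinstance(p, dict)
                else DeconditionParams(*p)
                for c, p in d["decondition_params"].items()
            }
        if "baseline_decades" in d:
            d["baseline_decades"] = tuple(d["baseline_decades"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted ground truth: class, cluster, drift curve and recovery position."""

    class_by_feature: pd.Series
    cluster_by_feature: pd.Series  # 1, 2 or 0 (none)
    drift_curve: pd.DataFrame  # features x injections, multiplicative
    recovery_position: pd.Series  # planted k; 0 for unaffected features

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.class_by_feature,
                "cluster": self.cluster_by_feature,
                "recovery_position": self.recovery_position,
            }
        ).rename_axis("feature_id")


def decondition_response(position: int, cluster: int, params: dict) -> float:
    """Multiplicative post-blank response at a conditioning position (1..8).

    Piecewise linear through (0, 1), (p_max, 1 + max_dev) and (k, 1);
    identically 1 from the recovery position k onward.
    """
    if not 1 <= position <= 8:
        raise ValueError("position must be in 1..8")
    p = params[cluster]
    if not isinstance(p, DeconditionParams):
        p = DeconditionParams(*p)
    if position >= p.k:
        return 1.0
    if position <= p.p_max:
        return 1.0 + p.max_dev * position / p.p_max
    return 1.0 + p.max_dev * (p.k - position) / (p.k - p.p_max)


def _build_sequence(config: SimulationConfig) -> pd.DataFrame:
    classes = ["QC"] * config.n_leading_qc
    for _ in range(config.n_cycles_intense):
        classes += ["blank"] * 3 + ["sample"] * 8
    for _ in range(config.n_cycles_mild):
        classes += ["blank"] + ["sample"] * 8
    seq = pd.DataFrame(
        {"run_order": np.arange(1, len(classes) + 1), "sample_class": classes}
    )
    return annotate_sequence(seq)


def _drift(rng, n_inj: int, amplitude: float) -> np.ndarray:
    """Smooth multiplicative drift: random low-order spline, |dev| <= amplitude."""
    if amplitude == 0 or n_inj < 2:
        return np.ones(n_inj)
    knots = np.linspace(1, n_inj, 5)
    vals = rng.uniform(-1, 1, size=5)
    s = CubicSpline(knots, vals)(np.arange(1, n_inj + 1))
    peak = np.abs(s).max()
    if peak > 0:
        s = s / peak * amplitude
    return 1.0 + s


def _lognormal_noise(rng, n: int, rsd: float) -> np.ndarray:
    if rsd == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(rsd**2))
    return np.exp(rng.normal(0.0, sigma, size=n))


def generate_batch(config: SimulationConfig) -> tuple[PeakTable, SyntheticTruth]:
    """Generate a peak table plus its planted truth; deterministic given seed.

    Each feature draws from its own random sub-stream (derived from the
    config seed and the feature index), so adding features leaves earlier
    features' data unchanged.
    """
    n_cycles = config.n_cycles_intense + config.n_cycles_mild
    if config.n_informative == 0 and n_cycles > 0:
        raise ValueError(
            "no informative features requested: conditioning assessment "
            "downstream would be undefined"
        )
    seq = _build_sequence(config)
    n_inj = len(seq)
    run_orders = seq.index

    sample_classes = seq["sample_class"].to_numpy()
    positions = seq["position_after_blank"].to_numpy()
    cycle_types = seq["cycle_type"].to_numpy()
    is_sample = sample_classes == "sample"
    is_blank = sample_classes == "blank"
    is_qc = sample_classes == "QC"

    labels, clusters = [], []
    for cls in FEATURE_CLASSES:
        cnt = config.n_features_by_class.get(cls, 0)
        labels += [cls] * cnt
        clusters += [
            1 if cls == "informative_cluster1" else 2 if cls == "informative_cluster2" else 0
        ] * cnt
    n_feat = len(labels)
    fids = [f"F{i + 1:04d}" for i in range(n_feat)]

    area = np.zeros((n_feat, n_inj))
    rt = np.zeros((n_feat, n_inj))
    width = np.zeros((n_feat, n_inj))
    detected = np.zeros((n_feat, n_inj), dtype=bool)
    drift_all = np.ones((n_feat, n_inj))
    mz = np.zeros(n_feat)
    rt_median = np.zeros(n_feat)
    recovery = np.zeros(n_feat, dtype=int)

    for i, cls in enumerate(labels):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i]))
        mz[i] = rng.uniform(100, 1200)
        lo, hi = RT_WINDOWS[cls]
        rt_median[i] = rng.uniform(lo, hi)
        base = 10 ** rng.uniform(*config.baseline_decades)
        base_width = rng.uniform(0.08, 0.25)
        drift = _drift(rng, n_inj, config.drift_amplitude)
        drift_all[i] = drift
        noise = _lognormal_noise(rng, n_inj, config.noise_rsd)
        w_noise = _lognormal_noise(rng, n_inj, config.width_noise_frac)
        rt_noise = rng.normal(0.0, config.rt_noise_minutes, size=n_inj)

        # deconditioning response and its normalised shape (for RT/width)
        response = np.ones(n_inj)
        shape = np.zeros(n_inj)
        cl = clusters[i]
        if cl:
            p = config.decondition_params[cl]
            recovery[i] = p.k
            for j in np.flatnonzero(is_sample):
                r = decondition_response(int(positions[j]), cl, config.decondition_params)
                if cycle_types[j] == "mild":
                    r = 1.0 + config.mild_attenuation * (r - 1.0)
                response[j] = r
                if p.max_dev > 0:
                    shape[j] = (r - 1.0) / p.max_dev

        rt[i] = rt_median[i] + rt_noise
        width[i] = base_width * w_noise
        if cls in INFORMATIVE_CLASSES:
            in_matrix = is_sample | is_qc
            area[i, in_matrix] = (base * drift * response * noise)[in_matrix]
            detected[i, in_matrix] = True
            # blanks: extraction blanks carry no analyte
            area[i, is_blank] = 0.0
            if cl == 2:
                rt[i] += config.rt_shift_minutes * shape
                width[i] *= 1.0 + config.width_shift_frac * shape
        elif cls == "contaminant":
            area[i] = base * drift * noise
            detected[i] = True
        else:  # carry-over +k
            k = int(cls[-1])
            det = np.zeros(n_inj, dtype=bool)
            level = np.zeros(n_inj)
            for j in range(n_inj):
                if is_blank[j] and cycle_types[j] != "leading":
                    b = int(positions[j])
                    if b <= k:
                        det[j] = True
                        level[j] = config.carryover_blank_decay ** (b - 1)
                elif is_sample[j] and cycle_types[j] != "leading":
                    if int(positions[j]) > k:
                        det[j] = True
                        level[j] = 1.0
            area[i, det] = (base * drift * noise)[det] * level[det]
            detected[i] = det

    features = pd.DataFrame({"mz": mz, "rt_median": rt_median}, index=pd.Index(fids, name="feature_id"))

    def _mat(m, dtype=float):
        return pd.DataFrame(m, index=features.index, columns=run_orders).astype(dtype)

    table = PeakTable(
        features=features,
        sequence=seq,
        area=_mat(area),
        rt=_mat(rt),
        width=_mat(width),
        detected=_mat(detected, bool),
    ).validate()
    truth = SyntheticTruth(
        class_by_feature=pd.Series(labels, index=features.index, name="class"),
        cluster_by_feature=pd.Series(clusters, index=features.index, name="cluster"),
        drift_curve=_mat(drift_all),
        recovery_position=pd.Series(recovery, index=features.index, name="recovery_position"),
    )
    return table, truth


def plasma_like(seed: int = 0, **overrides) -> SimulationConfig:
    """Plasma-style scenario: strong deconditioning, carry-over present."""
    return SimulationConfig(seed=seed, **overrides)


def urine_like(seed: int = 0, **overrides) -> SimulationConfig:
    """Urine-style scenario: blanks and matrix are alike in polarity, so no
    deconditioning response and no column carry-over; contaminants remain."""
    defaults = dict(
        n_features_by_class={
            "informative_stable": 150,
            "informative_cluster1": 0,
            "informative_cluster2": 0,
            "contaminant": 100,
            "carryover_1": 0,
            "carryover_2": 0,
            "carryover_3": 0,
        },
        rt_shift_minutes=0.0,
        width_shift_frac=0.0,
    )
    defaults.update(overrides)
    return SimulationConfig(seed=seed, **defaults)
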