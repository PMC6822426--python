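"""Synthetic pharmaco-proteomic data with known ground truth.

Emulates the statistical structure the modelling pipeline assumes: a
cell-line x protein abundance matrix built from one response-predictive
latent direction plus one response-orthogonal latent direction tied to a
binary tumor-type label, i.i.d. Gaussian measurement noise, and
feature-biased missingness; and viability-plate tables whose signals
follow a Hill inhibition curve around a nominal vehicle level.

The matrix model is

    X = t p' + s * t_o p_o' + noise,   t = standardized(y),  y ~ U(0, 1)

with t_o driven by the tumor-type label independently of y. Planted
predictive features carry signed unit loadings (sign = whether abundance
tracks sensitivity or resistance); orthogonal-factor features are a
disjoint set by default. With unit loadings and noise SD sigma the
univariate signal fraction per planted feature is 1/(1+sigma^2); the
default sigma = 0.5 targets approximately R^2 = 0.8 per planted feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix, ResponseVector

#: plate vehicle-signal level that synthetic plates are generated around
NOMINAL_VEHICLE = 10000.0
NOMINAL_BLANK = 150.0


@dataclass
class SyntheticSpec:
    """Knobs of the matrix generator; defaults mirror the study layout.

    ``n_planted`` features receive signed predictive loadings
    (``planted_signs``, alternating +/- by default: positive = higher
    abundance in sensitive lines). ``orthogonal_strength`` scales the
    tumor-type factor relative to the predictive signal; 0 disables it.
    """

    n_samples: int = 26
    n_features: int = 232
    n_planted: int = 10
    planted_signs: list[int] | None = None
    orthogonal_strength: float = 1.0
    n_orthogonal_features: int = 20
    noise_sd: float = 0.5
    missing_fraction: float = 0.10
    phospho_fraction: float = 0.25
    n_receptor: int = 16
    melanoma_fraction: float = 0.58
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_features:
            raise ValueError("more planted features than features")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.planted_signs is None:
            self.planted_signs = [1 if i % 2 == 0 else -1 for i in range(self.n_planted)]
        if len(self.planted_signs) != self.n_planted:
            raise ValueError("planted_signs length must equal n_planted")


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Benchmark regime: n=30 lines, p=200 features, 10 planted."""
    kw = dict(n_samples=30, n_features=200, n_planted=10, orthogonal_strength=1.0,
              seed=seed)
    kw.update(overrides)
    return SyntheticSpec(**kw)


def confounded_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Orthogonal tumor-type factor 3x the predictive signal strength."""
    kw = dict(n_samples=30, n_features=200, n_planted=10, orthogonal_strength=3.0,
              n_orthogonal_features=40, seed=seed)
    kw.update(overrides)
    return SyntheticSpec(**kw)


def null_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """No planted signal at all: response independent of the matrix."""
    kw = dict(n_samples=30, n_features=200, n_planted=0, orthogonal_strength=0.0,
              noise_sd=1.0, seed=seed)
    kw.update(overrides)
    return SyntheticSpec(**kw)


def generate_rppa_like(spec: SyntheticSpec):
    """Draw (FeatureMatrix, ResponseVector, ground_truth) from the spec.

    All randomness flows from ``spec.seed`` through a single Generator;
    repeated calls with the same spec are bit-identical. The ground-truth
    record lists planted/orthogonal feature ids with their loadings, the
    latent scores, and the per-sample tumor-type labels.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    sample_ids = [f"CL{i:03d}" for i in range(n)]
    feature_ids = [f"F{j:03d}" for j in range(p)]

    y = rng.uniform(0.0, 1.0, size=n)
    t = (y - y.mean()) / y.std(ddof=0)

    n_mel = max(1, int(round(spec.melanoma_fraction * n)))
    tumor = np.array(["melanoma"] * n_mel + ["non-melanoma"] * (n - n_mel))
    rng.shuffle(tumor)
    label = (tumor == "melanoma").astype(float)
    # standardized label + jitter, independent of y by construction
    t_o = label - label.mean()
    sd = t_o.std(ddof=0)
    if sd > 0:
        t_o = t_o / sd
    t_o = t_o + 0.25 * rng.standard_normal(n)

    loadings = np.zeros(p)
    planted_idx = np.arange(spec.n_planted)
    loadings[planted_idx] = np.asarray(spec.planted_signs, dtype=float)

    ortho_loadings = np.zeros(p)
    n_of = min(spec.n_orthogonal_features, p - spec.n_planted)
    ortho_idx = np.arange(spec.n_planted, spec.n_planted + n_of)
    ortho_loadings[ortho_idx] = 1.0

    X = (
        np.outer(t, loadings)
        + spec.orthogonal_strength * np.outer(t_o, ortho_loadings)
        + spec.noise_sd * rng.standard_normal((n, p))
    )

    values = pd.DataFrame(X, index=sample_ids, columns=feature_ids)
    if spec.missing_fraction > 0:
        # feature-biased missingness: a third of the mass concentrated on a
        # "poorly detected" subset, so the detection filter has real work
        per_feature = np.full(p, spec.missing_fraction * 2 / 3)
        n_poor = max(1, p // 10)
        poor = rng.choice(np.setdiff1d(np.arange(p), planted_idx), size=n_poor,
                          replace=False)
        per_feature[poor] = min(0.95, spec.missing_fraction * 2 / 3 + 0.5)
        mask = rng.uniform(size=(n, p)) < per_feature[None, :]
        values = values.mask(pd.DataFrame(mask, index=sample_ids, columns=feature_ids))

    n_ph = int(round(spec.phospho_fraction * p))
    kind = np.array(["total"] * p, dtype=object)
    ph_idx = rng.choice(p, size=n_ph, replace=False)
    kind[ph_idx] = "phospho"
    is_receptor = np.zeros(p, dtype=bool)
    rec_idx = rng.choice(p, size=min(spec.n_receptor, p), replace=False)
    is_receptor[rec_idx] = True
    feature_meta = pd.DataFrame({"kind": kind, "is_receptor": is_receptor},
                                index=feature_ids)
    sample_meta = pd.DataFrame({"tumor_type": tumor}, index=sample_ids)

    x = FeatureMatrix(values, feature_meta, sample_meta)
    resp = ResponseVector(pd.Series(y, index=sample_ids, name="auc"))
    truth = {
        "planted_features": [feature_ids[j] for j in planted_idx],
        "planted_loadings": {feature_ids[j]: float(loadings[j]) for j in planted_idx},
        "orthogonal_features": [feature_ids[j] for j in ortho_idx],
        "t": t,
        "t_o": t_o,
        "tumor_type": tumor,
        "spec": spec,
    }
    return x, resp, truth


# ---------------------------------------------------------------------------
# dose-response plates
# ---------------------------------------------------------------------------

def hill_inhibition(dose, ic50: float, hill: float):
    """Fractional-inhibition Hill curve on the percent scale."""
    dose = np.asarray(dose, dtype=float)
    return 100.0 / (1.0 + (ic50 / dose) ** hill)


def twofold_doses(top: float, n: int = 10) -> np.ndarray:
    """Two-fold serial dilution series descending from ``top`` (uM)."""
    return top / (2.0 ** np.arange(n))[::-1]


def generate_dose_response(
    true_ic50: float,
    true_hill: float,
    doses,
    noise_sd: float = 0.0,
    seed: int = 0,
    arm: str = "drug1",
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Simulate a viability plate arm with duplicate wells, vehicle and blanks.

    Signals are built by inverting the percent-inhibition transform
    around a nominal vehicle ATP level: a well at inhibition y%% reads
    ``blank + vehicle_level * (1 - y/100)`` plus Gaussian noise of
    ``noise_sd`` percent of the vehicle level.
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any():
        raise ValueError("treatment doses must be positive")
    rows = []
    for _ in range(n_replicates):
        for d in doses:
            inh = hill_inhibition(d, true_ic50, true_hill)
            signal = NOMINAL_BLANK + NOMINAL_VEHICLE * (1 - inh / 100.0)
            signal += noise_sd / 100.0 * NOMINAL_VEHICLE * rng.standard_normal()
            rows.append((arm, "treated", d, max(signal, 0.0)))
        vehicle = NOMINAL_BLANK + NOMINAL_VEHICLE
        vehicle += noise_sd / 100.0 * NOMINAL_VEHICLE * rng.standard_normal()
        rows.append((arm, "vehicle", 0.0, max(vehicle, 0.0)))
        rows.append((arm, "blank", 0.0, NOMINAL_BLANK))
    return pd.DataFrame(rows, columns=["arm", "well_type", "dose_uM", "signal"])


def generate_combo_experiment(
    mono1: tuple[float, float],
    mono2: tuple[float, float],
    interaction: float = 1.0,
    ratio: tuple[float, float] = (1, 2),
    doses=None,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Mono + fixed-ratio combination plates with a planted Loewe index.

    ``interaction`` is the true Loewe additivity index of the combination:
    1 additive, < 1 synergistic, > 1 antagonistic. With combination doses
    indexed by the drug-1 concentration c (drug-2 at ``ratio[1]/ratio[0]``
    times c), the combination IC50 c* satisfying
    ``c*/IC50_1 + r c*/IC50_2 = interaction`` is

        c* = interaction / (1/IC50_1 + r/IC50_2)

    Returns (plate1, plate2, combo_plate) DataFrames in the standard
    plate layout; the combo arm's ``dose_uM`` is the drug-1 axis.
    """
    if interaction <= 0:
        raise ValueError("interaction must be positive")
    ic50_1, hill_1 = mono1
    ic50_2, hill_2 = mono2
    r = ratio[1] / ratio[0]
    if doses is None:
        doses = twofold_doses(33.0, 10)
    combo_ic50 = interaction / (1.0 / ic50_1 + r / ic50_2)
    combo_hill = 0.5 * (hill_1 + hill_2)
    p1 = generate_dose_response(ic50_1, hill_1, doses, noise_sd, seed, arm="drug1")
    p2 = generate_dose_response(ic50_2, hill_2, np.asarray(doses) * r, noise_sd,
                                seed + 1, arm="drug2")
    pc = generate_dose_response(combo_ic50, combo_hill, doses, noise_sd, seed + 2,
                                arm="combo")
    return p1, p2, pc
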