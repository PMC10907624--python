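"""Synthetic screen, target-map, fingerprint, and dose–response generators.

These generators produce inputs with the statistical structure the analysis
pipeline assumes, so every downstream stage can be exercised and validated
without external data:

* :func:`simulate_screen` — a (patient + healthy) × drug inhibition matrix
  with two planted drug clusters. Patient samples split into two responder
  blocks and cluster-g drugs respond strongly on block g only, so the two
  cluster mean profiles differ by ``profile_separation`` noise-SDs on every
  patient sample; healthy-sample responses are an attenuated copy of each
  drug's patient-level effect (low attenuation = low toxicity); cells go
  missing i.i.d.
* :func:`simulate_target_map` — drugs hit proteins from two pools, with
  cluster-g drugs biased toward pool g.
* :func:`simulate_fingerprints` — binary fingerprints bit-flipped from a
  per-cluster seed pattern so intra-cluster Dice similarity hits a target.
* :func:`simulate_surface` — monotherapy Hill curves plus a combination grid
  drawn from a chosen null model, with an optional synergy shift.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .response import HEALTHY, PATIENT, RawScreen
from .chem import Fingerprint
from .synergy import DoseResponseSurface, HillParams
from .targets import DrugTargetMap

__all__ = [
    "ScreenSpec",
    "SurfaceSpec",
    "simulate_screen",
    "simulate_target_map",
    "simulate_fingerprints",
    "simulate_surface",
]

DEFAULT_DOSES = (1.0, 10.0, 100.0, 1000.0, 10000.0)  # nM


@dataclass
class ScreenSpec:
    """Parameters of a two-cluster synthetic drug-response screen.

    ``profile_separation`` is the planted effect size: the difference between
    the two cluster mean profiles on every patient sample, in units of
    ``noise_sd`` (cluster-g drugs respond at ``base_response`` +
    separation·noise_sd on their own responder block of samples, and at
    ``base_response`` elsewhere). ``healthy_attenuation`` bounds the per-drug attenuation
    factor (drawn Uniform(0, healthy_attenuation)) that scales each drug's
    patient-level mean response down on healthy samples; drugs with a low
    draw are the low-toxicity ones.
    ``drug_effect_sd`` adds per-drug potency jitter so drugs within a cluster
    differ in overall efficacy/toxicity.
    """

    n_patient: int = 40
    n_healthy: int = 10
    n_drugs_per_cluster: tuple[int, int] = (20, 20)
    profile_separation: float = 6.0
    noise_sd: float = 0.08
    missing_rate: float = 0.2
    healthy_attenuation: float = 0.5
    drug_effect_sd: float = 0.02
    base_response: float = 0.05  # off-block (non-responder) inhibition level
    seed: int = 0

    def validate(self) -> None:
        if self.n_patient < 1:
            raise ValueError("n_patient must be >= 1")
        if self.n_healthy < 1:
            raise ValueError("n_healthy must be >= 1")
        if any(n < 1 for n in self.n_drugs_per_cluster):
            raise ValueError("n_drugs_per_cluster entries must be >= 1")
        if self.profile_separation < 0:
            raise ValueError("profile_separation must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (0.0 <= self.healthy_attenuation <= 1.0):
            raise ValueError("healthy_attenuation must lie in [0, 1]")


@dataclass
class RawScreenTruth:
    """A simulated raw screen plus its planted ground truth."""

    screen: RawScreen
    planted_cluster: dict[str, int]  # drug id -> 1 or 2
    patient_profiles: np.ndarray  # (2, n_patient) planted cluster means


def simulate_screen(spec: ScreenSpec) -> RawScreenTruth:
    """Simulate a raw inhibition screen with two planted drug clusters.

    Patient responses for a cluster-g drug are μ_g[i] + drug offset +
    Gaussian noise, truncated to [0, 1], where μ_g is high
    (base + separation·noise_sd) on cluster g's responder block of patient
    samples and low (base) elsewhere — so the two cluster profiles differ by
    profile_separation noise-SDs on every patient sample. Healthy responses
    are a per-drug attenuation times the drug's patient-level mean, plus
    noise. Cells are masked missing i.i.d. at missing_rate.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_drugs_per_cluster
    n_d = n1 + n2
    n_s = spec.n_patient + spec.n_healthy

    # patient samples split into two responder blocks (alternating index);
    # cluster-g drugs respond at base + separation·noise_sd on block g and at
    # the low baseline elsewhere — each drug class is effective in its own
    # patient subpopulation, which is the structure the bipartite projection
    # is meant to detect
    hi = spec.base_response + spec.profile_separation * spec.noise_sd
    block = (np.arange(spec.n_patient) % 2) + 1  # sample i responds to cluster block[i]
    mu = np.vstack(
        [
            np.where(block == 1, hi, spec.base_response),
            np.where(block == 2, hi, spec.base_response),
        ]
    )

    cluster = np.array([1] * n1 + [2] * n2)
    drug_offset = rng.normal(0.0, spec.drug_effect_sd, size=n_d)
    # per-drug attenuation: low-toxicity drugs barely touch healthy samples,
    # high-toxicity ones approach healthy_attenuation × their patient effect
    attenuation = rng.uniform(0.0, spec.healthy_attenuation, size=n_d)

    values = np.empty((n_s, n_d))
    for j in range(n_d):
        prof = mu[cluster[j] - 1] + drug_offset[j]
        values[: spec.n_patient, j] = prof + rng.normal(
            0.0, spec.noise_sd, size=spec.n_patient
        )
        healthy_mean = attenuation[j] * float(np.mean(prof))
        values[spec.n_patient :, j] = healthy_mean + rng.normal(
            0.0, spec.noise_sd, size=spec.n_healthy
        )
    values = np.clip(values, 0.0, 1.0)

    if spec.missing_rate > 0:
        mask = rng.random((n_s, n_d)) < spec.missing_rate
        values = np.where(mask, np.nan, values)

    sample_ids = [f"P{i:03d}" for i in range(spec.n_patient)] + [
        f"H{i:03d}" for i in range(spec.n_healthy)
    ]
    drug_ids = [f"D{j:03d}" for j in range(n_d)]
    screen = RawScreen(
        values=values,
        sample_ids=sample_ids,
        drug_ids=drug_ids,
        sample_class=[PATIENT] * spec.n_patient + [HEALTHY] * spec.n_healthy,
    )
    return RawScreenTruth(
        screen=screen,
        planted_cluster={d: int(c) for d, c in zip(drug_ids, cluster)},
        patient_profiles=mu,
    )


def simulate_target_map(
    cluster_labels: dict[str, int],
    n_proteins: int = 200,
    bias: float = 0.9,
    targets_per_drug: int = 5,
    seed: int = 0,
) -> DrugTargetMap:
    """Simulate a cluster-biased drug → protein-target bipartite map.

    Proteins are split into two equal pools; each target of a cluster-g drug
    is drawn from pool g with probability ``bias`` (0.5 = no structure,
    1.0 = perfectly exclusive pools).
    """
    if not (0.5 <= bias <= 1.0):
        raise ValueError("bias must lie in [0.5, 1]")
    if n_proteins < 2:
        raise ValueError("need at least 2 proteins")
    rng = np.random.default_rng(seed)
    proteins = np.array([f"PR{i:04d}" for i in range(n_proteins)])
    pool = {1: proteins[: n_proteins // 2], 2: proteins[n_proteins // 2 :]}
    targets: dict[str, set[str]] = {}
    for drug in sorted(cluster_labels):
        g = cluster_labels[drug]
        own, other = (pool[1], pool[2]) if g == 1 else (pool[2], pool[1])
        chosen: set[str] = set()
        while len(chosen) < min(targets_per_drug, n_proteins):
            src = own if rng.random() < bias else other
            chosen.add(str(rng.choice(src)))
        targets[drug] = chosen
    return DrugTargetMap(targets=targets)


def simulate_fingerprints(
    cluster_labels: dict[str, int],
    n_bits: int = 1024,
    within_similarity: float = 0.8,
    seed: int = 0,
) -> list[Fingerprint]:
    """Simulate cluster-correlated binary fingerprints.

    Each cluster gets a random density-0.5 seed pattern; members flip every
    bit independently with probability q = (1 − sqrt(2s − 1))/2, which makes
    the expected intra-cluster Dice similarity exactly s = within_similarity
    (valid for s ≥ 0.5; the inter-cluster expectation stays at 0.5, the Dice
    of independent density-0.5 fingerprints). For s < 0.5 — below the random
    baseline — cluster structure is impossible under this scheme and
    fingerprints are drawn independently with bit density s instead.
    """
    if n_bits < 8:
        raise ValueError("n_bits must be >= 8")
    if not (0.0 < within_similarity <= 1.0):
        raise ValueError("within_similarity must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    fps = []
    if within_similarity < 0.5:
        warnings.warn(
            "within_similarity < 0.5 is below the random-fingerprint baseline; "
            "generating independent fingerprints with matching density"
        )
        for drug in sorted(cluster_labels):
            bits = np.where(rng.random(n_bits) < within_similarity)[0]
            fps.append(
                Fingerprint(drug_id=drug, on_bits=frozenset(bits.tolist()), n_bits=n_bits)
            )
        return fps
    q = 0.5 * (1.0 - np.sqrt(2.0 * within_similarity - 1.0))
    seeds = {
        c: rng.random(n_bits) < 0.5 for c in sorted(set(cluster_labels.values()))
    }
    for drug in sorted(cluster_labels):
        base = seeds[cluster_labels[drug]]
        flips = rng.random(n_bits) < q
        bits = np.where(base ^ flips)[0]
        fps.append(
            Fingerprint(drug_id=drug, on_bits=frozenset(bits.tolist()), n_bits=n_bits)
        )
    return fps


@dataclass
class SurfaceSpec:
    """Parameters of one synthetic dose–response combination surface."""

    hill_a: HillParams = field(
        default_factory=lambda: HillParams(e_min=0.0, e_max=0.9, ec50=100.0, slope=1.0)
    )
    hill_b: HillParams = field(
        default_factory=lambda: HillParams(e_min=0.0, e_max=0.8, ec50=300.0, slope=1.2)
    )
    dose_grid: tuple[float, ...] = DEFAULT_DOSES
    interaction: str = "bliss_independent"
    shift_delta: float = 0.0
    replicate_noise_sd: float = 0.0
    drug_a: str = "drugA"
    drug_b: str = "drugB"
    seed: int = 0

    def validate(self) -> None:
        d = np.asarray(self.dose_grid, dtype=float)
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("dose_grid must be strictly increasing and positive")
        if not (-1.0 <= self.shift_delta <= 1.0):
            raise ValueError("shift_delta must lie in [-1, 1]")
        if self.interaction not in (
            "bliss_independent",
            "hsa_max",
            "sham_self",
            "additive_shift",
        ):
            raise ValueError(f"unknown interaction model {self.interaction!r}")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be >= 0")


def simulate_surface(spec: SurfaceSpec) -> DoseResponseSurface:
    """Simulate a combination surface from Hill monotherapies + a null model.

    Combination cells equal the chosen null model's expectation plus
    ``shift_delta`` (a planted synergy/antagonism offset) plus replicate
    noise, truncated to [0, 1]. ``sham_self`` combines a drug with itself
    dose-additively (combo(x_a, x_b) = hill_a(x_a + x_b)), the exact Loewe
    null; it ignores ``hill_b``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    doses = np.asarray(spec.dose_grid, dtype=float)
    hill_b = spec.hill_a if spec.interaction == "sham_self" else spec.hill_b
    ya = np.asarray(spec.hill_a(doses))
    yb = np.asarray(hill_b(doses))

    if spec.interaction == "bliss_independent":
        combo = ya[:, None] + yb[None, :] - ya[:, None] * yb[None, :]
    elif spec.interaction == "hsa_max":
        combo = np.maximum(ya[:, None], yb[None, :])
    elif spec.interaction == "sham_self":
        total = doses[:, None] + doses[None, :]
        combo = np.asarray(spec.hill_a(total))
    else:  # additive_shift: response-additive null, capped at full effect
        combo = np.minimum(ya[:, None] + yb[None, :], 1.0)

    combo = combo + spec.shift_delta
    if spec.replicate_noise_sd > 0:
        n = doses.size
        ya = ya + rng.normal(0.0, spec.replicate_noise_sd, n)
        yb = yb + rng.normal(0.0, spec.replicate_noise_sd, n)
        combo = combo + rng.normal(0.0, spec.replicate_noise_sd, (n, n))
    return DoseResponseSurface(
        drug_a=spec.drug_a,
        drug_b=spec.drug_b if spec.interaction != "sham_self" else spec.drug_a + "'",
        doses_a=doses,
        doses_b=doses,
        mono_a=np.clip(ya, 0.0, 1.0),
        mono_b=np.clip(yb, 0.0, 1.0),
        combo=np.clip(combo, 0.0, 1.0),
    )
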