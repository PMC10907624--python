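"""End-to-end combination-design pipeline.

Stages, in order: ingest (or simulate) the raw screen → extract the complete
submatrix → normalize to inhibition rates → build the bipartite network →
project onto drugs → median-filter → Louvain clustering → corroboration
(protein-target scoring, chemical homogeneity; read-only with respect to the
clustering) → efficacy/toxicity profiling and candidate selection → pair the
selected drugs → dose–response surfaces per pair → synergy scores and
combination ratios on patient and healthy material → proportion tests.

Everything is seeded; a manifest of parameters and derived seeds is included
in the report so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem, network, response, selection, synergy, synthetic, targets

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "screen_scale_config"]


@dataclass
class PipelineConfig:
    """Single configuration object for the full pipeline.

    File inputs override the corresponding synthetic generators; with no
    files the run is fully synthetic from ``screen_spec``. Defaults mirror
    the study conditions: five-point dose ladder 1–10000 nM, PPT thresholds
    ±ln 2, top-5% selection with four drugs per cluster, null success
    probability 0.33.
    """

    screen_csv: str | None = None
    target_tsv: str | None = None
    fingerprint_tsv: str | None = None
    screen_spec: synthetic.ScreenSpec = field(default_factory=synthetic.ScreenSpec)
    normalization_scope: str = "global"
    submatrix_priority: str = "max_area"
    resolution: float = 1.0
    louvain_seed: int = 0
    ppt_threshold: float = math.log(2.0)
    selection_fraction: float = 0.05
    per_cluster: int = 4
    dose_grid: tuple[float, ...] = synthetic.DEFAULT_DOSES
    p0: float = 0.33
    # synthetic combination-screen conditions
    inter_patient_shift: float = 0.10
    intra_healthy_shift: float = 0.05
    surface_noise_sd: float = 0.02
    target_bias: float = 0.9
    n_proteins: int = 200
    within_similarity: float = 0.8
    homogeneity_permutations: int = 199
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if self.screen_csv is None:
            self.screen_spec.validate()
        if not (0 < self.selection_fraction <= 1):
            raise ValueError("selection_fraction must lie in (0, 1]")
        if not (0 < self.p0 < 1):
            raise ValueError("p0 must lie in (0, 1)")
        if self.per_cluster < 1:
            raise ValueError("per_cluster must be >= 1")


@dataclass
class RunReport:
    config: PipelineConfig
    matrix: response.ResponseMatrix
    similarity: network.DrugSimilarityNetwork
    clusters: network.ClusterAssignment
    planted_cluster: dict[str, int] | None
    protein_scores: list
    ppt1: set[str]
    ppt2: set[str]
    homogeneity: chem.HomogeneityResult | None
    profiles: list[selection.DrugProfile]
    selected: list[selection.DrugProfile]
    combinations: pd.DataFrame
    proportion_tests: dict[str, selection.ProportionTestResult]
    manifest: dict


def screen_scale_config(seed: int = 0) -> PipelineConfig:
    """Pipeline configuration at the scale of a real ex vivo AML screen.

    ~200 samples × ~600 drugs with light missingness, so the complete
    submatrix retains a few hundred drugs and the top-5% rule yields roughly
    a dozen candidates before the per-cluster cap — the regime in which four
    drugs per cluster and the 16-inter / 12-intra combination design emerge.
    """
    spec = synthetic.ScreenSpec(
        n_patient=160,
        n_healthy=40,
        n_drugs_per_cluster=(312, 312),
        profile_separation=6.0,
        noise_sd=0.08,
        missing_rate=0.01,
        healthy_attenuation=0.8,
        seed=seed,
    )
    return PipelineConfig(screen_spec=spec, seed=seed, louvain_seed=seed)


def _child_seed(seed: int, k: int) -> int:
    return int((seed * 9973 + k) % (2**31 - 1))


def _drug_hills(
    profiles: list[selection.DrugProfile], dose_grid, seed: int
) -> dict[str, tuple[synergy.HillParams, synergy.HillParams]]:
    """Per-drug (patient, healthy) Hill curves consistent with each drug's
    efficacy/toxicity profile: the maximal effect scales with the profile
    mean, the EC50 is drawn near the middle of the dose ladder."""
    rng = np.random.default_rng(seed)
    mid = float(np.sqrt(dose_grid[0] * dose_grid[-1]))
    out = {}
    for p in sorted(profiles, key=lambda q: q.drug_id):
        ec50 = mid * 10 ** rng.uniform(-0.5, 0.5)
        slope = rng.uniform(0.8, 1.5)
        e_pat = float(np.clip(1.6 * p.efficacy, 0.05, 1.0))
        e_hea = float(np.clip(1.6 * p.toxicity, 0.02, 1.0))
        out[p.drug_id] = (
            synergy.HillParams(e_min=0.0, e_max=e_pat, ec50=ec50, slope=slope),
            synergy.HillParams(e_min=0.0, e_max=e_hea, ec50=ec50, slope=slope),
        )
    return out


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full analysis; see the module docstring for the stage order."""
    config.validate()
    manifest: dict = {
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        }
    }

    # --- ingest ---------------------------------------------------------
    planted: dict[str, int] | None = None
    if config.screen_csv is not None:
        raw = response.read_screen_csv(config.screen_csv)
    else:
        truth = synthetic.simulate_screen(config.screen_spec)
        raw = truth.screen
        planted = truth.planted_cluster

    sub = response.extract_complete_submatrix(raw, priority=config.submatrix_priority)
    matrix = response.normalize_inhibition(sub, scope=config.normalization_scope)
    manifest["submatrix_shape"] = list(matrix.a.shape)

    # --- network + clustering ------------------------------------------
    bip = network.build_bipartite(matrix)
    sim = network.project_onto_drugs(bip)
    filt = network.filter_edges_median(sim)
    clusters = network.detect_communities(
        filt, resolution=config.resolution, seed=config.louvain_seed
    )
    manifest["filter_threshold"] = filt.filter_threshold
    manifest["n_communities"] = clusters.n_communities
    manifest["modularity"] = clusters.modularity

    # --- corroboration (read-only w.r.t. clustering) --------------------
    if config.target_tsv is not None:
        tmap = targets.read_target_tsv(config.target_tsv)
    else:
        gen_labels = planted if planted is not None else clusters.labels
        gen_labels = {d: c for d, c in gen_labels.items() if d in clusters.labels}
        tmap = synthetic.simulate_target_map(
            gen_labels,
            n_proteins=config.n_proteins,
            bias=config.target_bias,
            seed=_child_seed(config.seed, 1),
        )
    protein_scores: list = []
    ppt1: set[str] = set()
    ppt2: set[str] = set()
    try:
        protein_scores = targets.score_proteins(tmap, clusters)
        ppt1, ppt2 = targets.preferential_sets(
            protein_scores, threshold=config.ppt_threshold
        )
    except ValueError as exc:  # corroboration degrades gracefully
        manifest["target_scoring_warning"] = str(exc)

    if config.fingerprint_tsv is not None:
        fps = chem.read_fingerprint_tsv(config.fingerprint_tsv)
    else:
        gen_labels = planted if planted is not None else clusters.labels
        gen_labels = {d: c for d, c in gen_labels.items() if d in clusters.labels}
        fps = synthetic.simulate_fingerprints(
            gen_labels,
            within_similarity=config.within_similarity,
            seed=_child_seed(config.seed, 2),
        )
    homogeneity = None
    try:
        homogeneity = chem.homogeneity_test(
            fps,
            clusters,
            n_permutations=config.homogeneity_permutations,
            seed=_child_seed(config.seed, 3),
        )
    except ValueError as exc:
        manifest["homogeneity_warning"] = str(exc)

    # --- selection ------------------------------------------------------
    try:
        profiles = selection.profile_drugs(matrix, clusters)
        selected = selection.select_candidates(
            profiles, fraction=config.selection_fraction, per_cluster=config.per_cluster
        )
    except ValueError as exc:
        # e.g. submatrix extraction removed every healthy (or patient) sample:
        # clustering stands, but efficacy/toxicity selection cannot run
        manifest["selection_warning"] = str(exc)
        profiles = []
        selected = []
    manifest["n_selected"] = len(selected)

    # --- combination screen ---------------------------------------------
    pairs = selection.all_pairs([p.drug_id for p in selected])
    combos = pd.DataFrame()
    tests: dict[str, selection.ProportionTestResult] = {}
    if pairs:
        combos = selection.label_combinations(pairs, clusters)
        hills = _drug_hills(profiles, config.dose_grid, _child_seed(config.seed, 4))
        col = {d: j for j, d in enumerate(matrix.drug_ids)}
        pat = matrix.patient_index
        hea = matrix.healthy_index
        rows = []
        for idx, (d1, d2) in enumerate(pairs):
            group = combos.iloc[idx]["group"]
            row = {"drug1": d1, "drug2": d2, "group": group}
            # combination inhibition per sample: Bliss union of the two
            # drugs' measured profiles (complementary profiles -> larger
            # union), plus the planted interaction shifts
            a = matrix.a[:, col[d1]]
            b = matrix.a[:, col[d2]]
            union = a + b - a * b
            eff_shift = config.inter_patient_shift if group == "inter" else 0.0
            tox_shift = 0.0 if group == "inter" else config.intra_healthy_shift
            row["efficacy"] = float(np.clip(union[pat] + eff_shift, 0, 1).mean())
            row["toxicity"] = float(np.clip(union[hea] + tox_shift, 0, 1).mean())
            for side, shift in (
                ("patient", eff_shift),
                ("healthy", tox_shift),
            ):
                hsel = 0 if side == "patient" else 1
                spec = synthetic.SurfaceSpec(
                    hill_a=hills[d1][hsel],
                    hill_b=hills[d2][hsel],
                    dose_grid=config.dose_grid,
                    interaction="bliss_independent",
                    shift_delta=shift,
                    replicate_noise_sd=config.surface_noise_sd,
                    drug_a=d1,
                    drug_b=d2,
                    seed=_child_seed(config.seed, 100 + 2 * idx + hsel),
                )
                surf = synthetic.simulate_surface(spec)
                for model in synergy.MODELS:
                    row[f"{model}_{side}"] = synergy.synergy_score(surf, model).score
                _, cr_mean, _ = synergy.combination_ratio(surf)
                row[f"cr_{side}"] = cr_mean
            rows.append(row)
        combos = pd.DataFrame(rows)

        if (combos["group"] == "inter").any():
            tests["inhibition"] = selection.proportion_test(
                combos, metric_pair=("efficacy", "toxicity"), p0=config.p0
            )
            for model in synergy.MODELS:
                tests[model] = selection.proportion_test(
                    combos,
                    metric_pair=(f"{model}_patient", f"{model}_healthy"),
                    p0=config.p0,
                )
            tests["cr"] = selection.proportion_test(
                combos, metric_pair=("cr_patient", "cr_healthy"), p0=config.p0
            )
    manifest["n_combinations"] = len(combos)
    if planted is not None:
        manifest["planted_labels_available"] = True

    report = RunReport(
        config=config,
        matrix=matrix,
        similarity=filt,
        clusters=clusters,
        planted_cluster=planted,
        protein_scores=protein_scores,
        ppt1=ppt1,
        ppt2=ppt2,
        homogeneity=homogeneity,
        profiles=profiles,
        selected=selected,
        combinations=combos,
        proportion_tests=tests,
        manifest=manifest,
    )
    if config.out_dir is not None:
        _write_outputs(report, Path(config.out_dir))
    return report


def _write_outputs(report: RunReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.matrix.to_frame().to_csv(out / "response_matrix.csv")
    report.similarity.to_edge_frame().to_csv(
        out / "drug_similarity_edges.tsv", sep="\t", index=False
    )
    report.clusters.to_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
    prof = pd.DataFrame(
        [
            {
                "drug": p.drug_id,
                "cluster": p.cluster,
                "efficacy": p.efficacy,
                "toxicity": p.toxicity,
                "selected": p.drug_id in {s.drug_id for s in report.selected},
            }
            for p in report.profiles
        ]
    )
    prof.to_csv(out / "profiles.tsv", sep="\t", index=False)
    if len(report.combinations):
        report.combinations.to_csv(out / "combinations.tsv", sep="\t", index=False)
    tests = {
        name: dataclasses.asdict(res) for name, res in report.proportion_tests.items()
    }
    (out / "proportion_tests.json").write_text(json.dumps(tests, indent=2))
    (out / "manifest.json").write_text(json.dumps(report.manifest, indent=2, default=str))
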