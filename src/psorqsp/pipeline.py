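"""End-to-end virtual-trial orchestration.

One run generates a virtual population, assigns comorbidity tags, builds an
individualized PK model per patient, simulates every dosing arm on the same
patients (n_patients x n_arms patient-arm models), converts exposure into
synthetic protein activities, scores tSignal, clusters the models,
characterizes the clusters demographically and molecularly, and (optionally)
runs annotation enrichment with network export.  A manifest records seeds,
versions, record counts and a checksum per output file; re-running the same
config and seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import activity as activity_mod
from . import cluster as cluster_mod
from . import enrichment as enrichment_mod
from . import pbpk, tsignal as tsignal_mod, vpop

__all__ = ["TrialConfig", "run_trial", "make_fixtures"]

STAGES = ("population", "comorbidity", "groups", "activity", "clustering",
          "bootstrap", "classifier", "enrichment")


@dataclass(frozen=True)
class TrialConfig:
    population: vpop.PopulationSpec
    heights: vpop.HeightModel = field(default_factory=vpop.HeightModel)
    comorbidities: tuple = ()
    arms: tuple = ("czp200", "czp400")
    scenario: activity_mod.MechanisticScenario = field(
        default_factory=lambda: activity_mod.MechanisticScenario(
            n_groups=3, effect_shift=0.5, noise_sd=0.1)
    )
    definition: activity_mod.ProteinDefinition | None = None
    cluster_config: cluster_mod.ClusterConfig = field(
        default_factory=cluster_mod.ClusterConfig
    )
    n_bootstrap: int = 100
    classifier_permutations: int = 100
    dt: float = 0.1
    seed: int = 0
    gmt_path: str | None = None
    graph_path: str | None = None
    link_threshold: float = 3.0

    def __post_init__(self) -> None:
        if len(set(self.arms)) != len(self.arms):
            raise ValueError("arm labels must be unique")
        for p in (self.gmt_path, self.graph_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _stage_seeds(global_seed: int) -> dict:
    """Deterministic per-stage seeds split from the global seed, so one
    stage's consumption never reshuffles another's."""
    root = np.random.SeedSequence(global_seed)
    children = root.spawn(len(STAGES))
    return {name: int(ss.generate_state(1)[0] % (2**31))
            for name, ss in zip(STAGES, children)}


def _regimen(label: str) -> pbpk.Regimen:
    if label.startswith("czp"):
        return pbpk.czp_regimen(int(label[3:]))
    raise ValueError(f"unknown regimen label {label!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_trial(config: TrialConfig, outdir) -> dict:
    """Run the full virtual trial; returns the manifest dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    definition = config.definition or activity_mod.synthetic_definition(
        124, seed=seeds["activity"]
    )
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "global_seed": config.seed,
        "stage_seeds": seeds,
        "arms": list(config.arms),
        "counts": {},
        "files": {},
    }

    def _fail(stage: str, record: str, exc: Exception):
        raise RuntimeError(f"stage {stage!r} failed at {record!r}: {exc}") from exc

    # --- population -------------------------------------------------------
    patients = vpop.generate_population(config.population, config.heights,
                                        seed=seeds["population"])
    patients = vpop.assign_comorbidities(patients, list(config.comorbidities),
                                         seed=seeds["comorbidity"])
    vpop.write_patients_csv(patients, out / "patients.csv")
    manifest["counts"]["patients"] = len(patients)

    # --- PBPK per patient-arm --------------------------------------------
    profile_rows, exposure_rows = [], []
    for arm in config.arms:
        regimen = _regimen(arm)
        for p in patients:
            try:
                params = pbpk.individualize(p)
                prof = pbpk.simulate(params, regimen, dt=config.dt,
                                     patient_id=p.id)
            except Exception as exc:
                _fail("pbpk", f"{p.id}/{arm}", exc)
            profile_rows.append(pd.DataFrame({
                "patient_id": p.id, "regimen": arm,
                "time_day": prof.times, "conc_mg_per_L": prof.concentrations,
            }))
            exposure_rows.append({
                "patient_id": p.id, "arm": arm,
                "exposure": activity_mod.exposure_summary(prof),
            })
    profiles = pd.concat(profile_rows, ignore_index=True)
    profiles.to_csv(out / "profiles.csv", index=False, float_format="%.8g")
    exposures = pd.DataFrame(exposure_rows)
    exposures.to_csv(out / "exposures.csv", index=False, float_format="%.10g")
    manifest["counts"]["patient_arm_models"] = len(exposures)

    # --- synthetic activities & tSignal ----------------------------------
    groups = activity_mod.assign_groups(patients, config.scenario,
                                        seed=seeds["groups"])
    matrix = activity_mod.generate_activity(
        patients, exposures, definition, config.scenario,
        seed=seeds["activity"], groups=groups,
    )
    matrix.to_tsv(out / "activity.tsv", out / "arms.csv")
    definition.to_csv(out / "definition.csv")
    ts = tsignal_mod.tsignal_per_model(matrix, definition)
    ts.to_frame().to_csv(out / "tsignal.csv", index_label="model_id",
                         float_format="%.10g")
    pd.Series(groups, name="group").to_csv(out / "groups.csv",
                                           index_label="patient_id")

    # --- clustering -------------------------------------------------------
    centered = cluster_mod.normalize_by_arm(matrix.values, matrix.arms)
    solutions = cluster_mod.cluster_grid(centered, [config.cluster_config],
                                         seed=seeds["clustering"])
    sol = solutions[0]
    report = cluster_mod.quality(sol.embedding, sol,
                                 n_bootstrap=config.n_bootstrap,
                                 seed=seeds["bootstrap"])
    pd.DataFrame({"model_id": matrix.values.index, "cluster": sol.labels}).to_csv(
        out / "cluster_labels.csv", index=False)
    indices = {
        "config": sol.config.describe(),
        "selected_k": sol.k,
        "best_k_per_index": sol.best_k,
        "index_table": json.loads(sol.index_table.to_json(orient="index")),
        "quality": {"hopkins": report.hopkins, "dunn": report.dunn,
                    "jaccard_bootstrap": report.jaccard_bootstrap},
    }
    (out / "indices.json").write_text(json.dumps(indices, indent=2, sort_keys=True))
    manifest["counts"]["clusters"] = int(sol.k)

    dist = cluster_mod.intercluster_distances(sol.embedding, sol.labels)
    dist.to_csv(out / "intercluster_distances.csv", float_format="%.10g")

    patient_frame = vpop.patients_to_frame(patients).set_index("id")
    row_patients = patient_frame.loc[
        [mid.rsplit("_", 1)[0] for mid in matrix.values.index]
    ].reset_index()
    charac = cluster_mod.characterize_clusters(sol.labels, row_patients,
                                               matrix.arms)
    charac.to_csv(out / "characterization.csv", index=False, float_format="%.10g")

    diff = cluster_mod.differential_proteins(centered, sol.labels)
    diff.to_csv(out / "differential_proteins.csv", index=False,
                float_format="%.10g")
    clf = cluster_mod.classifier_proteins(
        centered, sol.labels, n_permutations=config.classifier_permutations,
        seed=seeds["classifier"],
    )
    clf.to_csv(out / "classifier_proteins.csv", index=False, float_format="%.10g")

    # --- enrichment -------------------------------------------------------
    if config.gmt_path and config.graph_path:
        collection = enrichment_mod.read_gmt(config.gmt_path)
        graph = enrichment_mod.read_edge_list(config.graph_path)
        universe = list(matrix.values.columns)
        all_results = []
        selected = diff[diff["selected"]]
        for (c, direction), block in selected.groupby(["cluster", "direction"]):
            res = enrichment_mod.enrich(
                set(block["protein"]) & set(universe), collection, universe,
                direction=direction, cluster=int(c),
            )
            all_results.extend(res)
        enr_frame = pd.DataFrame([r.__dict__ for r in all_results])
        enr_frame.to_csv(out / "enrichment.csv", index=False)
        net = enrichment_mod.build_network(all_results, collection, graph,
                                           config.link_threshold,
                                           universe=universe)
        enrichment_mod.write_sif(net, out / "enrichment_network.sif")
        enrichment_mod.write_graphml(net, out / "enrichment_network.graphml")
        enrichment_mod.node_attribute_table(net).to_csv(
            out / "enrichment_nodes.csv", index=False)
        manifest["counts"]["enriched_sets"] = len(all_results)

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixtures(outdir, seed: int = 0) -> dict:
    """Write small deterministic input files: a 20-patient population spec,
    a 12-protein toy definition, a 3-set GMT and a 10-node interaction
    graph.  Idempotent under a fixed seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    spec_yaml = {
        "n_patients": 20,
        "female_fraction": 0.344,
        "age": {"mean": 45.53, "sd": 13.23},
        "weight": {"mean": 90.73, "sd": 22.71},
        "bmi": {"mean": 30.48, "sd": 7.07},
        "comorbidities": [
            {"name": "obesity", "frequency": 0.3, "eligibility_rule": "bmi_gt_30"},
            {"name": "diabetes_t2", "frequency": 0.0438},
        ],
    }
    (out / "population.yaml").write_text(yaml.safe_dump(spec_yaml, sort_keys=True))

    definition = activity_mod.synthetic_definition(12, seed=seed, label="toy")
    definition.to_csv(out / "definition.csv")

    ids = definition.ids
    sets = []
    for i in range(3):
        members = sorted(rng.choice(ids, size=10, replace=False))
        sets.append((f"pathway{i + 1}", frozenset(members)))
    enrichment_mod.write_gmt(
        enrichment_mod.AnnotationCollection(tuple(sets), source="toy"),
        out / "pathways.gmt",
    )

    nodes = ids[:10]
    lines = []
    for i in range(len(nodes) - 1):  # path backbone keeps it connected
        lines.append(f"{nodes[i]}\t{nodes[i + 1]}")
    for _ in range(5):
        a, b = rng.choice(nodes, size=2, replace=False)
        lines.append(f"{a}\t{b}")
    (out / "network.tsv").write_text("\n".join(lines) + "\n")

    return {"outdir": str(out),
            "files": sorted(p.name for p in out.iterdir() if p.is_file())}
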