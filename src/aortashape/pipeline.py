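"""End-to-end pipeline orchestration.

``run_pipeline`` drives mesh loading (or simulation), surface sampling,
rigid alignment and template construction, PCA, morphometrics,
mode-descriptor correlations, the surgery-risk models and cluster
analysis, writing every stage artifact (HDF5 atlas, CSV tables, PNG
figures, log) into a run directory.  Runs are deterministic given the
config and seed; the expensive sample-align-PCA stage is cached, keyed by
a content hash of its inputs, so reruns resume cheaply.

``shape_risk_study`` is the replicated experiment comparing the
shape-mode surgery model against the diameter-only baseline over many
simulated cohorts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment, atlas as atlas_mod, morphometrics, sampling, stats, strain, synthetic
from .errors import ConfigError
from .mesh_io import CohortTable, SurfaceMesh, read_cohort, read_mesh

logger = logging.getLogger("aortashape")


@dataclass
class PipelineConfig:
    """All tunables of one run; plain-text ``key = value`` serializable."""

    out_dir: str = "run"
    mesh_dir: str = ""              # directory of per-subject meshes (ignored when simulating)
    cohort_csv: str = ""
    simulate_n: int = 0             # >0: generate a synthetic cohort instead of loading
    simulate_controls: int = 0
    n_points: int = sampling.DEFAULT_N_POINTS
    seed: int = 0
    variance_threshold: float = 0.90
    icp_max_iter: int = alignment.DEFAULT_ICP_MAX_ITER
    icp_tol: float = alignment.DEFAULT_ICP_TOL
    template_max_rounds: int = alignment.DEFAULT_MAX_ROUNDS
    dilatation_cutoff: float = morphometrics.DEFAULT_DILATATION_CUTOFF
    k_clusters: str = "auto"

    def validate(self) -> "PipelineConfig":
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ConfigError(
                f"variance_threshold must be in (0, 1], got {self.variance_threshold}"
            )
        for name in ("icp_tol",):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.n_points < sampling.MIN_N_POINTS:
            raise ConfigError(f"n_points must be >= {sampling.MIN_N_POINTS}")
        return self

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        values: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ConfigError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            values[key] = type(current)(val) if not isinstance(current, str) else val
        return cls(**values).validate()


def _content_hash(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, np.ndarray):
            h.update(np.ascontiguousarray(p).tobytes())
        else:
            h.update(str(p).encode())
    return h.hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    if config.simulate_n > 0:
        sim = synthetic.simulate_cohort(
            n_ataa=config.simulate_n,
            n_control=config.simulate_controls,
            seed=config.seed,
        )
        return sim.meshes, sim.cohort, sim
    cohort = read_cohort(config.cohort_csv)
    mesh_dir = Path(config.mesh_dir)
    meshes = []
    for sid in cohort.subject_ids:
        candidates = [mesh_dir / f"{sid}{ext}" for ext in (".stl", ".ply", ".obj")]
        found = next((c for c in candidates if c.exists()), None)
        if found is None:
            raise FileNotFoundError(
                f"no mesh found for subject {sid!r} in {mesh_dir} (tried .stl/.ply/.obj)"
            )
        meshes.append(read_mesh(found, subject_id=sid))
    return meshes, cohort, None


def build_atlas_from_meshes(
    meshes: list[SurfaceMesh],
    cohort: CohortTable | None = None,
    n_points: int = 2000,
    seed: int = 0,
    icp_max_iter: int = alignment.DEFAULT_ICP_MAX_ITER,
    icp_tol: float = alignment.DEFAULT_ICP_TOL,
    template_max_rounds: int = alignment.DEFAULT_MAX_ROUNDS,
):
    """Sample, align, correspond and decompose a mesh population.

    Returns ``(atlas, template, transforms)``.  The initial reference is
    the subject nearest the mean mid-ascending diameter when the cohort
    provides diameters, else the subject of median bounding-box size.

    Poses come from tube-frame landmark registration (arc-length-matched
    centerline stations plus ellipse-axis tips): ordered anatomical
    correspondence pins all six degrees of freedom, where closest-point
    ICP would let a dilated or deflated subject slide along the curved
    channel.  Correspondence then probes each pose-aligned subject
    *surface* along the fixed outward normals of an N-point reference
    probe cloud, and each atlas point is the probe point displaced by the
    signed normal distance to the subject wall.  Measuring only the
    normal displacement is what makes the decomposition robust: wall
    dilatation of +/-10 mm makes full 3D closest-point matching slide
    tangentially, which manufactures spurious bilinear "interaction"
    modes next to the genuine small modes, while the normal component
    carries the whole signal for wall-displacement variation.  A probe
    offset from the population mean only shifts each point's displacement
    by a constant, which PCA's centering removes.

    When landmark extraction fails (non-tubular input), the pipeline
    falls back to cloud ICP with centerline- or multi-start
    initialization and 3D closest-point correspondence.
    """
    if cohort is not None and cohort.has("diameter_midaa") and not cohort.column("diameter_midaa").isna().any():
        ref = alignment.select_initial_reference(cohort)
        ref_idx = [m.subject_id for m in meshes].index(ref)
    else:
        ref_idx = int(np.argmin(np.abs(
            [np.linalg.norm(np.ptp(m.vertices, axis=0)) for m in meshes]
            - np.mean([np.linalg.norm(np.ptp(m.vertices, axis=0)) for m in meshes])
        )))
        ref = ref_idx
    poses = _landmark_poses(meshes, ref_idx)
    if poses is not None:
        from ._geometry import closest_point_on_mesh

        aligned_meshes = [
            SurfaceMesh(t.apply(m.vertices), m.faces, m.subject_id)
            for m, t in zip(meshes, poses)
        ]
        probe = sampling.resample_surface(aligned_meshes[ref_idx], n_points, seed)
        q, normals = probe.points, probe.normals
        corresponded = []
        for m in aligned_meshes:
            feet, _ = closest_point_on_mesh(m, q)
            h = np.sum((feet - q) * normals, axis=1)
            corresponded.append(q + h[:, None] * normals)
        corresponded = np.stack(corresponded)
        transforms = poses
        template = alignment.Template(
            points=corresponded.mean(axis=0), iteration_count=1, converged=True, history=[]
        )
        subject_ids = [m.subject_id for m in meshes]
    else:
        seeds = np.random.SeedSequence(seed).generate_state(len(meshes)) % (2**31)
        clouds = [
            sampling.resample_surface(m, n_points, int(s)) for m, s in zip(meshes, seeds)
        ]
        inits = _centerline_inits(meshes, ref_idx)
        template, transforms = alignment.build_template(
            clouds, reference=ref, max_rounds=template_max_rounds,
            icp_max_iter=icp_max_iter, icp_tol=icp_tol, init_transforms=inits,
        )
        corresponded = []
        for c, t in zip(clouds, transforms):
            y = alignment.correspond(template.points, t.apply(c.points))
            corresponded.append(alignment.kabsch(y, template.points).apply(y))
        corresponded = np.stack(corresponded)
        subject_ids = [c.subject_id for c in clouds]
    shape_atlas = atlas_mod.fit_pca(corresponded, subject_ids=subject_ids)
    return shape_atlas, template, transforms


def _radius_profile(mesh: SurfaceMesh, centerline, n_bins: int = 20) -> np.ndarray:
    """Mean vertex-to-centerline distance per arc-length band."""
    from scipy.spatial import cKDTree

    fine = centerline.resample(400)
    dist, idx = cKDTree(fine.points).query(mesh.vertices)
    band = np.clip((fine.fractions[idx] * n_bins).astype(int), 0, n_bins - 1)
    prof = np.array([dist[band == b].mean() if (band == b).any() else np.nan for b in range(n_bins)])
    # fill any empty band from its neighbours
    if np.isnan(prof).any():
        ok = np.isfinite(prof)
        prof = np.interp(np.arange(n_bins), np.nonzero(ok)[0], prof[ok])
    return prof


def _landmark_poses(meshes: list[SurfaceMesh], ref_idx: int):
    """Per-subject tube-frame landmark poses into the reference frame."""
    try:
        lms = [alignment.tube_frame_landmarks(m) for m in meshes]
        ref = lms[ref_idx]
        return [alignment.tube_frame_pose(lm, ref) for lm in lms]
    except Exception as exc:  # noqa: BLE001 - fall back to ICP alignment
        logger.warning("tube-frame landmark registration unavailable (%s); "
                       "falling back to ICP", exc)
        return None


def _centerline_inits(meshes: list[SurfaceMesh], ref_idx: int):
    """Per-subject centerline-guided round-0 ICP seeds (None on failure)."""
    try:
        cls = [strain.extract_centerline(m) for m in meshes]
        profs = [_radius_profile(m, c) for m, c in zip(meshes, cls)]
        ref_cl, ref_prof = cls[ref_idx], profs[ref_idx]
        return [
            alignment.centerline_guided_init(c.points, p, ref_cl.points, ref_prof)
            for c, p in zip(cls, profs)
        ]
    except Exception as exc:  # noqa: BLE001 - fall back to multi-start ICP
        logger.warning("centerline-guided initialization unavailable (%s); "
                       "falling back to principal-axis multi-start", exc)
        return None


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        config.to_file(out / "config.txt")
        meshes, cohort, _sim = _load_inputs(config)
        logger.info("loaded %d meshes, %d cohort rows", len(meshes), cohort.n_subjects)

        # ---- sample + align + PCA (cached by content hash) ----
        key = _content_hash(
            config.n_points, config.seed, config.icp_tol, config.icp_max_iter,
            config.template_max_rounds, *[m.vertices for m in meshes],
        )
        atlas_path = out / "atlas.h5"
        hash_path = out / "atlas.hash"
        if atlas_path.exists() and hash_path.exists() and hash_path.read_text() == key:
            shape_atlas = atlas_mod.load_atlas(atlas_path)
            logger.info("atlas stage: reused cached result (%s)", key)
        else:
            shape_atlas, template, _ = build_atlas_from_meshes(
                meshes, cohort, n_points=config.n_points, seed=config.seed,
                icp_max_iter=config.icp_max_iter, icp_tol=config.icp_tol,
                template_max_rounds=config.template_max_rounds,
            )
            atlas_mod.save_atlas(shape_atlas, atlas_path, metadata={"seed": config.seed, "hash": key})
            hash_path.write_text(key)
            logger.info(
                "atlas stage: template converged=%s after %d rounds",
                template.converged, template.iteration_count,
            )
        n90 = atlas_mod.modes_for_variance(shape_atlas, config.variance_threshold)
        logger.info("modes retained at %.0f%% variance: %d", 100 * config.variance_threshold, n90)
        atlas_mod.scree_table(shape_atlas).to_csv(out / "scree.csv", index=False)
        _plot_scree(shape_atlas, out / "scree.png")

        # ---- morphometrics ----
        profiles = []
        for mesh in meshes:
            try:
                cl = strain.extract_centerline(mesh)
                profiles.append(morphometrics.measure_profile(mesh, cl, cutoff=config.dilatation_cutoff).__dict__)
            except Exception as exc:  # noqa: BLE001 - per-subject stage failure is reported, not fatal
                logger.warning("morphometrics failed for %s: %s", mesh.subject_id, exc)
        morpho_df = pd.DataFrame(profiles)
        morpho_df.to_csv(out / "morphometrics.csv", index=False)

        # ---- correlations ----
        desc_cols = [
            c for c in ("diameter_midaa", "orifice_area", "flow_jet", "wss_stj", "strain_midaa", "tortuosity")
            if cohort.has(c)
        ]
        descriptors = cohort.df[desc_cols].reset_index(drop=True)
        n_corr_modes = min(n90, 6, shape_atlas.n_modes)
        corr = stats.correlate_modes(shape_atlas.scores[:, :n_corr_modes], descriptors)
        corr.insert(0, "correction", "none")
        corr.to_csv(out / "correlations.csv", index=False)

        # ---- risk models ----
        if cohort.has("surgery") and cohort.column("surgery").nunique() == 2:
            y = cohort.column("surgery").to_numpy().astype(bool)
            model_modes = stats.fit_risk_model(
                y, atlas=shape_atlas, predictor="modes_90",
                variance_threshold=config.variance_threshold,
            )
            diam = cohort.column("diameter_midaa").to_numpy()
            model_diam = stats.fit_risk_model(y, diameter=diam, predictor="diameter")
            pd.DataFrame(
                {
                    "predictor": ["modes_90", "diameter"],
                    "auc": [model_modes.auc, model_diam.auc],
                    "n_predictors": [model_modes.n_predictors, 1],
                    "ridge_active": [model_modes.ridge_active, model_diam.ridge_active],
                }
            ).to_csv(out / "risk_models.csv", index=False)
            pd.DataFrame(
                {"fpr": model_modes.roc_fpr, "tpr": model_modes.roc_tpr}
            ).to_csv(out / "roc_modes.csv", index=False)
            pd.DataFrame(
                {"fpr": model_diam.roc_fpr, "tpr": model_diam.roc_tpr}
            ).to_csv(out / "roc_diameter.csv", index=False)
            _plot_roc(model_modes, model_diam, out / "roc.png")
            logger.info("AUC modes_90=%.3f diameter=%.3f", model_modes.auc, model_diam.auc)
        else:
            logger.info("surgery labels absent or single-class; risk models skipped")

        # ---- clusters + group summary ----
        clusters = stats.cluster_scores(shape_atlas.scores, k=config.k_clusters, seed=config.seed)
        pd.DataFrame(
            {"subject_id": shape_atlas.subject_ids, "cluster": clusters.labels}
        ).to_csv(out / "clusters.csv", index=False)
        logger.info("clusters: k=%d silhouette=%.3f", clusters.k, clusters.silhouette)
        if cohort.has("group") and (cohort.column("group") == "control").any():
            summary = stats.group_mode_summary(
                shape_atlas.scores[:, 0], cohort.column("group").to_numpy()
            )
            summary.to_csv(out / "mode1_by_group.csv", index=False)

        (out / "summary.json").write_text(
            json.dumps(
                {
                    "n_subjects": len(meshes),
                    "n_points": config.n_points,
                    "n_modes_retained": int(n90),
                    "mode1_variance_fraction": float(shape_atlas.variance_fractions[0]),
                    "elapsed_s": round(time.time() - t0, 2),
                },
                indent=2,
            )
        )
        logger.info("pipeline finished in %.1fs", time.time() - t0)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def _plot_scree(shape_atlas, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = atlas_mod.scree_table(shape_atlas)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(t["mode"], 100 * t["variance_fraction"], color="steelblue", label="per mode")
    ax.plot(t["mode"], 100 * t["cumulative_fraction"], "o-", color="firebrick", label="cumulative")
    ax.axhline(90, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("shape mode")
    ax.set_ylabel("variance explained (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_roc(model_modes, model_diam, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(model_modes.roc_fpr, model_modes.roc_tpr, label=f"shape modes (AUC={model_modes.auc:.3f})")
    ax.plot(model_diam.roc_fpr, model_diam.roc_tpr, label=f"diameter (AUC={model_diam.auc:.3f})")
    ax.plot([0, 1], [0, 1], ":", c="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(frameon=False, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Replicated risk-model experiment
# ---------------------------------------------------------------------------

def shape_risk_study(
    n_subjects: int = 200,
    n_replicates: int = 50,
    seed: int = 0,
    variance_threshold: float = 0.90,
    axial_resolution: int = 40,
    circumferential_resolution: int = 16,
) -> pd.DataFrame:
    """Shape-mode versus diameter-only surgery models over simulated cohorts.

    Each replicate draws a fresh cohort (surgery labels from the logistic
    link on the three principal mode weights), builds the PCA atlas from
    the subject surfaces, fits both logistic models and records their
    in-sample AUCs.  The population uses the extended six-field basis —
    three principal modes carrying the surgery signal plus three minor
    nuisance modes — so its eigenvalue spectrum has the long tail real
    anatomies show; with a bare three-mode spectrum the 90% rule would
    retain only two modes and the comparison would pit a misspecified
    shape model against the diameter.  Replicates run without rigid
    perturbation and use the mesh vertices as corresponded clouds —
    alignment robustness is certified by the dedicated alignment and
    mode-recovery checks — which keeps many replicates tractable.

    Returns a DataFrame with one row per replicate:
    ``auc_modes, auc_diameter, n_modes_retained, prevalence``.
    """
    spec = synthetic.AortaSpec(
        axial_resolution=axial_resolution,
        circumferential_resolution=circumferential_resolution,
    )
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rows = []
    for rs in rep_seeds:
        sim = synthetic.simulate_cohort(
            n_ataa=n_subjects, spec=spec, seed=int(rs), rigid_perturbation=False,
            basis_kind="extended",
            mode_sds=(4.0, 2.0, 1.2, 0.9, 0.7, 0.5),
            logistic_beta=synthetic.DEFAULT_LOGISTIC_BETA + (0.0, 0.0, 0.0),
        )
        clouds = np.stack([m.vertices for m in sim.meshes])
        a = atlas_mod.fit_pca(clouds, subject_ids=[m.subject_id for m in sim.meshes])
        y = sim.cohort.column("surgery").to_numpy().astype(bool)
        if y.sum() < 2 or (~y).sum() < 2:
            continue
        model_modes = stats.fit_risk_model(
            y, atlas=a, predictor="modes_90", variance_threshold=variance_threshold
        )
        diam = sim.cohort.column("diameter_midaa").to_numpy()
        model_diam = stats.fit_risk_model(y, diameter=diam, predictor="diameter")
        # both AUCs are asserted against the rank-sum oracle inside fit_risk_model
        rows.append(
            {
                "auc_modes": model_modes.auc,
                "auc_diameter": model_diam.auc,
                "n_modes_retained": model_modes.n_predictors,
                "prevalence": float(y.mean()),
            }
        )
    return pd.DataFrame(rows)
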