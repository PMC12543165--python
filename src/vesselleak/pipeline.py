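"""End-to-end orchestration: simulate -> segment/classify -> shells ->
traces/indices -> embedding/diagnostics -> permeability, with config
serialization and a manifest for provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, embedding, hemodynamics, phantom, traces, vasculature
from .core import save_json

logger = logging.getLogger(__name__)


class DependencyError(RuntimeError):
    """A stage ran without its upstream artifact."""


@dataclass
class RunConfig:
    out_dir: str = "runs/latest"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    compute_indices: bool = True
    embed: bool = True
    diagnostics: bool = True
    permeability: bool = True
    # phantom
    volume_shape: tuple[int, int, int] = (16, 72, 72)
    frame_interval_s: float = 90.0
    capillary_density: float = 3.0
    group_sizes: dict = field(default_factory=lambda: {"Control": 4, "SE": 4, "NI": 3})
    noise_sigma: float = 1.0
    vignette_strength: float = 0.0
    psf_fwhm_um: float = 1.0
    # analysis parameters
    r_in_um: float = 5.0
    r_out_um: float = 15.0
    baseline_frames: int = 5
    min_roi_voxels: int = 20
    n_neighbors: int = 5
    min_dist: float = 0.4
    umap_seed: int = 42
    k_clusters: int = 3
    kmeans_n_init: int = 100
    fit_start_min: float = 5.0
    hematocrit: float = 0.45

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "volume_shape" in data:
            data["volume_shape"] = tuple(data["volume_shape"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["volume_shape"] = list(d["volume_shape"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def analyze_animal(animal: dict, cfg: RunConfig):
    """Shells + traces + conventional indices for one virtual animal.

    Uses the truth lumen partition (segmentation and graph construction
    have their own validation path); returns
    ``(index_table, feature_matrix, traces)`` or None when no vessel
    survives the ROI filters.
    """
    truth = animal["truth"]
    stack = animal["stack"]
    rois, shell_labels = vasculature.perivascular_shells(
        truth.lumen_mask, truth.labels, truth.voxel_size_um,
        cfg.r_in_um, cfg.r_out_um,
    )
    trs = traces.extract_traces(stack, shell_labels, truth.labels,
                                min_roi_voxels=cfg.min_roi_voxels)
    table, matrix = traces.compute_indices(trs, baseline_frames=cfg.baseline_frames)
    if table.empty:
        return None
    meta = truth.segment_table.set_index("id")
    table["vessel_class"] = meta.loc[table["segment_id"], "vessel_class"].to_numpy()
    table["true_Ktrans"] = meta.loc[table["segment_id"], "true_Ktrans"].to_numpy()
    table["diameter_um"] = meta.loc[table["segment_id"], "diameter_um"].to_numpy()
    table["true_velocity_mm_s"] = meta.loc[table["segment_id"], "true_velocity_mm_s"].to_numpy()
    table["roi_volume_um3"] = [rois[s].volume_um3 for s in table["segment_id"]]
    table["animal_id"] = animal["animal_id"]
    table["condition"] = animal["condition"]
    return table, matrix, trs


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order; returns the bundle.

    Artifacts (CSV/JSON plus the verbatim config) land in
    ``config.out_dir``; a manifest with content hashes makes reruns
    comparable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    bundle: dict = {"out_dir": str(out)}
    artifacts: list[Path] = [out / "config.yaml"]

    if not config.simulate:
        raise DependencyError("pipeline currently requires the simulate stage "
                              "(external inputs go through the CLI subcommands)")

    spec = phantom.PhantomSpec(
        volume_shape=config.volume_shape,
        frame_interval_s=config.frame_interval_s,
        capillary_density=config.capillary_density,
        seed=config.seed,
    )
    kin = phantom.KineticsSpec(
        noise_sigma=config.noise_sigma,
        vignette_strength=config.vignette_strength,
        psf_fwhm_um=config.psf_fwhm_um,
    )
    animals = phantom.simulate_cohort(spec, kin, config.group_sizes, seed=config.seed)
    bundle["animals"] = animals
    seg_tables = []
    for a in animals:
        st = a["truth"].segment_table.copy()
        st["animal_id"] = a["animal_id"]
        st["condition"] = a["condition"]
        seg_tables.append(st)
    seg_all = pd.concat(seg_tables, ignore_index=True)
    seg_all.to_csv(out / "segments.csv", index=False)
    artifacts.append(out / "segments.csv")

    if not config.compute_indices:
        bundle["manifest"] = _write_manifest(out, artifacts, config)
        return bundle

    tables, matrices, trace_lists = [], [], []
    for a in animals:
        result = analyze_animal(a, config)
        if result is None:
            logger.warning("animal %s: no vessels survived filtering", a["animal_id"])
            continue
        tab, mat, trs = result
        tables.append(tab)
        matrices.append(mat)
        trace_lists.append(trs)
    if not tables:
        raise DependencyError("indices stage produced no vessels")
    index_table = pd.concat(tables, ignore_index=True)
    matrix = np.vstack(matrices)
    index_cols = ["segment_id", "vessel_class", "condition", "animal_id",
                  "auc", "dff0", "dfdt"]
    index_table[index_cols].to_csv(out / "indices.csv", index=False)
    artifacts.append(out / "indices.csv")
    bundle["indices"] = index_table
    bundle["matrix"] = matrix

    if config.embed:
        emb = embedding.embed_umap(matrix, config.n_neighbors, config.min_dist,
                                   seed=config.umap_seed)
        control = (index_table["condition"] == "Control").to_numpy()
        classes = index_table["vessel_class"].to_numpy()
        index_table["umap_dist"] = embedding.umap_distance(emb.coords, control, classes)
        labels, comp_group, comp_class = embedding.kmeans_clusters(
            emb.coords, index_table["condition"].to_numpy(), classes,
            k=config.k_clusters, seed=config.umap_seed, n_init=config.kmeans_n_init,
        )
        emb_df = pd.DataFrame({
            "segment_id": index_table["segment_id"],
            "animal_id": index_table["animal_id"],
            "u1": emb.coords[:, 0], "u2": emb.coords[:, 1],
            "cluster": labels, "umap_dist": index_table["umap_dist"],
        })
        emb_df.to_csv(out / "embedding.csv", index=False)
        comp_group.to_csv(out / "cluster_composition.csv")
        artifacts += [out / "embedding.csv", out / "cluster_composition.csv"]
        bundle["embedding"] = emb
        bundle["clusters"] = labels
        bundle["cluster_composition"] = comp_group

    if config.diagnostics:
        if "umap_dist" not in index_table:
            raise DependencyError("diagnostics requires the embed stage")
        diag = []
        for vclass in ("arteriole", "capillary", "venule"):
            sub = index_table[index_table["vessel_class"] == vclass]
            if sub.empty:
                continue
            for idx_name in ("auc", "dff0", "dfdt", "umap_dist"):
                for positive in ("SE", "NI"):
                    try:
                        r = embedding.roc_diagnostic(
                            sub[idx_name].to_numpy(), sub["condition"].to_numpy(),
                            positive, unit="per_animal",
                            animal_ids=sub["animal_id"].to_numpy(),
                        )
                    except ValueError:
                        continue
                    diag.append({
                        "vessel_class": vclass, "index": idx_name,
                        "positive": positive, "roc_auc": r.roc_auc,
                        "U": r.mann_whitney_U, "p": r.p_value, "unit": r.unit,
                    })
        save_json(diag, out / "diagnostics.json")
        artifacts.append(out / "diagnostics.json")
        bundle["diagnostics"] = diag

    if config.permeability:
        perm_rows = []
        for a, tab, trs in zip(animals, tables, trace_lists):
            for _, row in tab.iterrows():
                tr = next(t for t in trs
                          if t.segment_id == row["segment_id"] and t.F0 is not None)
                try:
                    res = hemodynamics.permeability_for_segment(
                        int(row["segment_id"]), tr.F, tr.F_iv, tr.t_min,
                        row["diameter_um"], row["true_velocity_mm_s"],
                        row["roi_volume_um3"], Hct=config.hematocrit,
                        fit_start_min=config.fit_start_min,
                    )
                except ValueError as e:
                    logger.warning("permeability skipped for %s/%s: %s",
                                   a["animal_id"], row["segment_id"], e)
                    continue
                perm_rows.append({
                    "animal_id": a["animal_id"], "condition": a["condition"],
                    "segment_id": res.segment_id, "vessel_class": row["vessel_class"],
                    "Ktrans_per_min": res.Ktrans, "vb": res.v_b, "r2": res.r2,
                    "PS_per_min": res.PS, "Fp_per_min": res.F_p_per_min,
                    "negative_slope": res.negative_slope,
                    "flow_limited": res.flow_limited,
                })
        perm = pd.DataFrame(perm_rows)
        perm.to_csv(out / "permeability.csv", index=False)
        artifacts.append(out / "permeability.csv")
        bundle["permeability"] = perm

    bundle["manifest"] = _write_manifest(out, artifacts, config)
    return bundle


def cohort_umap_rocs(
    seed: int,
    volume_shape: tuple[int, int, int] = (16, 72, 72),
    frame_interval_s: float = 90.0,
    capillary_density: float = 25.0,
    group_sizes: dict | None = None,
    umap_seed: int = 42,
) -> dict:
    """Per-animal ROC of the class-stratified UMAP distance on one
    simulated cohort: SE-like disease read out on arterioles, NI-like on
    venules. No files are written; everything is in memory.
    """
    cfg = RunConfig(out_dir="unused", seed=seed, volume_shape=volume_shape,
                    frame_interval_s=frame_interval_s,
                    capillary_density=capillary_density)
    spec = phantom.PhantomSpec(volume_shape=volume_shape,
                               frame_interval_s=frame_interval_s,
                               capillary_density=capillary_density, seed=seed)
    kin = phantom.KineticsSpec()
    animals = phantom.simulate_cohort(spec, kin, group_sizes, seed=seed)
    tables, matrices = [], []
    for a in animals:
        result = analyze_animal(a, cfg)
        if result is None:
            continue
        tab, mat, _ = result
        tables.append(tab)
        matrices.append(mat)
    table = pd.concat(tables, ignore_index=True)
    matrix = np.vstack(matrices)
    emb_res = embedding.embed_umap(matrix, cfg.n_neighbors, cfg.min_dist, seed=umap_seed)
    control = (table["condition"] == "Control").to_numpy()
    classes = table["vessel_class"].to_numpy()
    table["umap_dist"] = embedding.umap_distance(emb_res.coords, control, classes)
    out = {}
    for positive, vclass in (("SE", "arteriole"), ("NI", "venule")):
        sub = table[table["vessel_class"] == vclass]
        r = embedding.roc_diagnostic(
            sub["umap_dist"].to_numpy(), sub["condition"].to_numpy(), positive,
            unit="per_animal", animal_ids=sub["animal_id"].to_numpy())
        out[f"{positive}_{vclass}"] = r.roc_auc
    out["table"] = table
    return out


def index_cohort_spearman(
    seed: int,
    ktrans_levels: tuple[float, ...] = (0.001, 0.0025, 0.004, 0.0055, 0.007),
    n_per_level: int = 30,
    noise_sigma: float = 2.5,
    ktrans_jitter_sd: float = 0.15,
    n_neighbors: int = 5,
    min_dist: float = 0.4,
    umap_seed: int = 42,
) -> float:
    """Mean Spearman correlation between the UMAP-distance index and the
    conventional indices on one trace-level phantom cohort.

    The cohort imitates the statistics of real single-vessel data:
    overlapping leakage levels with measurement noise comparable to the
    level spacing, so the neighbor graph stays connected and the
    embedding preserves the leakage ordering. Levels that are orders of
    magnitude apart produce isolated UMAP islands whose relative
    placement is arbitrary — a failure mode of the distance index, not
    of the generator.
    """
    from scipy import stats as sstats

    t = np.linspace(0, 60, 241)
    rng = np.random.default_rng(seed)
    kin = phantom.KineticsSpec(noise_sigma=noise_sigma)
    rows, idx = [], {"auc": [], "dff0": [], "dfdt": []}
    i = 0
    for kt0 in ktrans_levels:
        for _ in range(n_per_level):
            kt = kt0 * rng.lognormal(0.0, ktrans_jitter_sd)
            _, cp = phantom.simulate_trace_pair(kt, kin, t, seed=seed * 100000 + i)
            i += 1
            F = kin.background + cp
            f = F / F[:5].mean()
            rows.append(f)
            idx["auc"].append(traces.index_auc(f, t))
            idx["dff0"].append(traces.index_dff0(f, t))
            idx["dfdt"].append(traces.index_dfdt(f, t))
    control = np.zeros(len(rows), bool)
    control[:n_per_level] = True
    res = embedding.embed_umap(embedding.build_feature_matrix(rows),
                               n_neighbors, min_dist, seed=umap_seed)
    d = embedding.umap_distance(res.coords, control)
    return float(np.mean([sstats.spearmanr(d, idx[k]).statistic for k in idx]))


def cluster_regime_ari(
    seed: int,
    ktrans_regimes: tuple[float, ...] = (0.002, 0.02, 0.06),
    n_per_regime: int = 8,
    noise_sigma: float = 0.4,
    umap_seed: int = 42,
) -> float:
    """Adjusted Rand index of k-means (k = number of regimes) on the
    UMAP embedding of one synthetic leakage-regime cohort.

    Small tight regimes keep each regime a single embedding island, so
    cluster recovery probes the clustering path rather than UMAP's
    arbitrary placement of fragmented islands.
    """
    from sklearn.metrics import adjusted_rand_score

    kin = phantom.KineticsSpec(noise_sigma=noise_sigma)
    t = np.linspace(0, 60, 241)
    rows, regime = [], []
    s = seed
    for g, kt in enumerate(ktrans_regimes):
        for _ in range(n_per_regime):
            _, cp = phantom.simulate_trace_pair(kt, kin, t, seed=s)
            s += 1
            F = kin.background + cp
            rows.append(F / F[:5].mean())
            regime.append(g)
    res = embedding.embed_umap(embedding.build_feature_matrix(rows), seed=umap_seed)
    labels, _, _ = embedding.kmeans_clusters(
        res.coords, np.asarray(regime).astype(str),
        k=len(ktrans_regimes), seed=umap_seed)
    return float(adjusted_rand_score(regime, labels))


def _write_manifest(out: Path, artifacts: list[Path], config: RunConfig) -> dict:
    manifest = {
        "vesselleak_version": __version__,
        "seed": config.seed,
        "umap_seed": config.umap_seed,
        "files": {p.name: _sha256(p) for p in artifacts if p.exists()},
    }
    save_json(manifest, out / "manifest.json")
    return manifest
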