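"""Config-driven end-to-end runner.

Stages: synth -> features -> encode -> catmap -> cluster -> semantics ->
layers. Every stage writes plain-text outputs plus a manifest entry with
sha256 checksums; a completed stage is skipped (and its outputs reloaded)
when resuming.
"""
from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catmap as cm
from . import cluster as cl
from . import encoding as enc
from . import features as feat
from . import io as ncio
from . import layers as ly
from . import semantics as sem
from . import synth

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "validate_config",
           "load_config", "STAGES"]

STAGES = ["synth", "features", "encode", "catmap", "cluster", "semantics", "layers"]

DEFAULT_THRESHOLDS = {"variance": 0.99, "q": 0.01, "r": 0.2, "alpha": 0.01,
                      "block_length": 20.0}
DEFAULT_PERMUTATIONS = {"accuracy": 500, "modularity": 1000, "semantic": 1000}


@dataclass
class PipelineConfig:
    generator: synth.GeneratorConfig = field(default_factory=synth.GeneratorConfig)
    hierarchy: synth.CategoryHierarchySpec = field(default_factory=synth.CategoryHierarchySpec)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    permutations: dict = field(default_factory=lambda: dict(DEFAULT_PERMUTATIONS))
    k_range: tuple = (2, 8)
    n_random_exemplars: int = 2000
    n_ceiling_sim: int = 1000
    n_restarts: int = 50
    seed: int = 0

    def __post_init__(self):
        t = dict(DEFAULT_THRESHOLDS)
        t.update(self.thresholds)
        self.thresholds = t
        p = dict(DEFAULT_PERMUTATIONS)
        p.update(self.permutations)
        self.permutations = p


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    gen = synth.GeneratorConfig(**raw.get("generator", {}))
    hie = synth.CategoryHierarchySpec(**raw.get("hierarchy", {}))
    kw = {k: v for k, v in raw.items() if k not in ("generator", "hierarchy")}
    if "k_range" in kw:
        kw["k_range"] = tuple(kw["k_range"])
    return PipelineConfig(generator=gen, hierarchy=hie, **kw)


def validate_config(raw: dict) -> list:
    """Report-only invariant check; returns a list of violation messages."""
    issues = []
    try:
        cfg = config_from_dict(raw)
    except (ValueError, TypeError, KeyError) as e:
        return [f"config does not parse: {e}"]
    t = cfg.thresholds
    if not (0 < t["variance"] <= 1):
        issues.append(f"thresholds.variance = {t['variance']} outside (0, 1] "
                      "(stage: features PCA)")
    for key in ("q", "alpha"):
        if not (0 < t[key] < 1):
            issues.append(f"thresholds.{key} = {t[key]} outside (0, 1)")
    if not (-1 <= t["r"] < 1):
        issues.append(f"thresholds.r = {t['r']} is not a usable correlation threshold")
    if t["block_length"] < 2 * cfg.generator.tr:
        issues.append("thresholds.block_length below two TRs (stage: encode permutation)")
    n_cat = len(cfg.hierarchy.category_labels)
    kmin, kmax = cfg.k_range
    if not (2 <= kmin <= kmax <= n_cat - 1):
        issues.append(f"k_range {cfg.k_range} outside 2..{n_cat - 1} for "
                      f"{n_cat} categories (stage: cluster)")
    for name, n in cfg.permutations.items():
        if n < 100:
            issues.append(f"permutations.{name} = {n} below the minimum of 100")
    if cfg.n_random_exemplars < 2:
        issues.append("n_random_exemplars must be at least 2 (stage: cluster region)")
    return issues


@dataclass
class RunManifest:
    stages: list = field(default_factory=list)

    def add(self, name: str, outputs: dict, seed: int, elapsed: float):
        self.stages.append({"stage": name, "outputs": outputs, "seed": seed,
                            "wall_clock_s": round(elapsed, 3)})

    def checksums(self) -> dict:
        return {f"{s['stage']}/{k}": v for s in self.stages for k, v in s["outputs"].items()}


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage_outputs(workdir: Path, files: list) -> dict:
    return {f: _sha256(workdir / f) for f in files}


# ---------------------------------------------------------------- stages ---

def _stage_synth(cfg: PipelineConfig, d: Path, ctx: dict):
    g, h = cfg.generator, cfg.hierarchy
    ctx["kernel"] = feat.hrf_kernel(g.time_step)
    ctx["movie"] = synth.make_layered_features(g, h)
    ctx["truth"] = synth.make_voxel_population(g)
    ctx["train_raw"], ctx["test_raw"] = synth.simulate_responses(
        ctx["movie"], ctx["truth"], ctx["kernel"], g)
    ctx["atlas"] = synth.make_category_exemplars(h, g)
    ctx["taxonomy"] = synth.make_toy_taxonomy(h)
    ctx["vectors"] = synth.make_label_vectors(h.category_labels, h, seed=g.seed)
    ctx["random_exemplars"] = synth.make_random_exemplars(
        g, cfg.n_random_exemplars, seed=g.seed + 1)

    ncio.write_series(d, "movie", ctx["movie"])
    ncio.write_matrix(d / "truth_weights.tsv", ctx["truth"].weights)
    ncio.write_matrix(d / "truth_preferred_layer.tsv", ctx["truth"].preferred_layer)
    ncio.write_matrix(d / "truth_noise_variance.tsv", ctx["truth"].noise_variance)
    for tag in ("train", "test"):
        resp = ctx[f"{tag}_raw"]
        ncio.write_matrix(d / f"responses_{tag}.tsv", resp.values)
        ncio.write_matrix(d / f"sessions_{tag}.tsv", resp.sessions)
    for ri, rep in enumerate(ctx["test_raw"].repeats):
        ncio.write_matrix(d / f"responses_test_repeat{ri:02d}.tsv", rep)
    for c in ctx["atlas"].categories:
        ncio.write_series(d / "exemplars", c, ctx["atlas"].exemplar_features[c])
    ncio.write_json(d / "exemplar_counts.json", ctx["atlas"].exemplar_counts)
    ncio.write_series(d / "exemplars", "random", ctx["random_exemplars"])
    ncio.write_taxonomy(d / "taxonomy.tsv", ctx["taxonomy"])
    ncio.write_vectors(d / "vectors.tsv", ctx["vectors"])
    files = ["truth_weights.tsv", "responses_train.tsv", "responses_test.tsv",
             "taxonomy.tsv", "vectors.tsv", "exemplar_counts.json"]
    return _stage_outputs(d, files)


def _load_synth(cfg: PipelineConfig, d: Path, ctx: dict):
    g, h = cfg.generator, cfg.hierarchy
    ctx["kernel"] = feat.hrf_kernel(g.time_step)
    ctx["movie"] = ncio.read_series(d, "movie")
    ctx["truth"] = synth.GroundTruthVoxels(
        weights=ncio.read_matrix(d / "truth_weights.tsv"),
        preferred_layer=ncio.read_matrix(d / "truth_preferred_layer.tsv").ravel().astype(int),
        noise_variance=ncio.read_matrix(d / "truth_noise_variance.tsv").ravel(),
        units_per_layer=g.units_per_layer)
    for tag in ("train", "test"):
        vals = ncio.read_matrix(d / f"responses_{tag}.tsv")
        sess = ncio.read_matrix(d / f"sessions_{tag}.tsv").ravel().astype(int)
        reps = None
        if tag == "test":
            reps = np.stack([ncio.read_matrix(d / f"responses_test_repeat{ri:02d}.tsv")
                             for ri in range(g.n_test_repeats)])
        ctx[f"{tag}_raw"] = enc.VoxelResponses(values=vals, sessions=sess, tr=g.tr,
                                               repeats=reps)
    counts = ncio.read_json(d / "exemplar_counts.json")
    cats = h.category_labels
    ctx["atlas"] = cm.CategoryAtlas(
        categories=cats,
        exemplar_features={c: ncio.read_series(d / "exemplars", c) for c in cats},
        exemplar_counts=counts)
    ctx["random_exemplars"] = ncio.read_series(d / "exemplars", "random")
    ctx["taxonomy"] = ncio.read_taxonomy(d / "taxonomy.tsv")
    ctx["vectors"] = ncio.read_vectors(d / "vectors.tsv")


def _stage_features(cfg: PipelineConfig, d: Path, ctx: dict):
    g = cfg.generator
    t_train_native = g.n_train_sessions * g.session_length * g.steps_per_tr
    movie = ctx["movie"]
    train_feats = feat.LayeredFeatureSeries(
        [m[:t_train_native] for m in movie.layers], time_step=movie.time_step)
    test_feats = feat.LayeredFeatureSeries(
        [m[t_train_native:] for m in movie.layers], time_step=movie.time_step)
    prep_train, std = feat.prepare_series(train_feats, ctx["kernel"], g.tr)
    prep_test, _ = feat.prepare_series(test_feats, ctx["kernel"], g.tr, standardizers=std)
    bases = feat.fit_pca(prep_train, cfg.thresholds["variance"], standardizers=std)
    ctx.update(prep_train=prep_train, prep_test=prep_test, standardizers=std, bases=bases)
    ctx["design_train"] = feat.transform(prep_train, bases)
    ctx["design_test"] = feat.transform(prep_test, bases)
    ncio.write_series(d, "prepared_train", prep_train)
    ncio.write_series(d, "prepared_test", prep_test)
    ncio.write_json(d / "standardizers.json", {
        "means": [m.tolist() for m in std.means], "sds": [s.tolist() for s in std.sds]})
    for i, b in enumerate(bases.layer_bases, start=1):
        ncio.write_matrix(d / f"basis_layer{i:02d}.tsv", b)
    ncio.write_matrix(d / "basis_cross.tsv", bases.cross_basis)
    ncio.write_json(d / "bases.json", {
        "layer_kept": [int(q) for q in bases.layer_kept],
        "cross_kept": int(bases.cross_kept),
        "variance_threshold": bases.variance_threshold,
        "units_per_layer": list(bases.units_per_layer),
        "layer_explained": [float(e) for e in bases.layer_explained],
        "cross_explained": float(bases.cross_explained)})
    ncio.write_matrix(d / "design_train.tsv", ctx["design_train"].matrix)
    ncio.write_matrix(d / "design_test.tsv", ctx["design_test"].matrix)
    return _stage_outputs(d, ["design_train.tsv", "design_test.tsv", "bases.json"])


def _load_features(cfg: PipelineConfig, d: Path, ctx: dict):
    ctx["prep_train"] = ncio.read_series(d, "prepared_train")
    ctx["prep_test"] = ncio.read_series(d, "prepared_test")
    sj = ncio.read_json(d / "standardizers.json")
    std = feat.Standardizers(means=[np.array(m) for m in sj["means"]],
                             sds=[np.array(s) for s in sj["sds"]])
    bj = ncio.read_json(d / "bases.json")
    bases = feat.PcaBases(
        layer_bases=[ncio.read_matrix(d / f"basis_layer{i:02d}.tsv")
                     for i in range(1, len(bj["layer_kept"]) + 1)],
        layer_kept=bj["layer_kept"],
        cross_basis=ncio.read_matrix(d / "basis_cross.tsv"),
        cross_kept=bj["cross_kept"],
        variance_threshold=bj["variance_threshold"],
        units_per_layer=tuple(bj["units_per_layer"]),
        layer_means=std.means, layer_sds=std.sds,
        layer_explained=bj["layer_explained"], cross_explained=bj["cross_explained"])
    ctx.update(standardizers=std, bases=bases)
    ctx["design_train"] = feat.FeatureDesign(matrix=ncio.read_matrix(d / "design_train.tsv"))
    ctx["design_test"] = feat.FeatureDesign(matrix=ncio.read_matrix(d / "design_test.tsv"))


def _stage_encode(cfg: PipelineConfig, d: Path, ctx: dict):
    g = cfg.generator
    train = enc.preprocess_responses(ctx["train_raw"])
    test = enc.preprocess_responses(ctx["test_raw"])
    model = enc.fit_ridge(ctx["design_train"], train)
    pred = enc.predict(model, ctx["design_test"], sessions=test.sessions, tr=g.tr)
    report = enc.accuracy(pred, test)
    report.p = enc.block_permutation_test(
        pred, test, block_length=cfg.thresholds["block_length"],
        n_perm=cfg.permutations["accuracy"], seed=cfg.seed)
    report.q = enc.fdr(report.p, alpha=cfg.thresholds["q"])
    report.ceiling = enc.noise_ceiling(ctx["test_raw"], n_sim=cfg.n_ceiling_sim,
                                       seed=cfg.seed)
    report.layer_r2 = enc.layer_explained_variance(model, ctx["bases"],
                                                   ctx["prep_test"], test)
    report.assigned_layer, report.layer_confident = enc.assign_layer(report.layer_r2)
    ctx.update(model=model, report=report, test_proc=test)
    ncio.write_matrix(d / "weights.tsv", model.weights)
    ncio.write_json(d / "model.json", {
        "lambda": model.lam if np.isscalar(model.lam) else np.asarray(model.lam).tolist(),
        "lambda_grid": np.asarray(model.lambda_grid).tolist(),
        "cv_table": np.asarray(model.cv_table).tolist()})
    table = pd.DataFrame({
        "voxel": np.arange(len(report.r)), "r": report.r, "p": report.p,
        "q": report.q, "ceiling": report.ceiling,
        "r_normalized": report.r_normalized,
        "assigned_layer": report.assigned_layer})
    table.to_csv(d / "accuracy_report.tsv", sep="\t", index=False, float_format="%.17g")
    ncio.write_matrix(d / "layer_r2.tsv", report.layer_r2)
    return _stage_outputs(d, ["weights.tsv", "accuracy_report.tsv", "layer_r2.tsv"])


def _load_encode(cfg: PipelineConfig, d: Path, ctx: dict):
    mj = ncio.read_json(d / "model.json")
    lam = mj["lambda"]
    ctx["model"] = enc.EncodingModel(
        weights=ncio.read_matrix(d / "weights.tsv"),
        lam=lam if np.isscalar(lam) else np.array(lam),
        cv_table=np.array(mj["cv_table"]), lambda_grid=np.array(mj["lambda_grid"]))
    t = pd.read_csv(d / "accuracy_report.tsv", sep="\t")
    test = enc.preprocess_responses(ctx["test_raw"])
    report = enc.AccuracyReport(r=t["r"].to_numpy(), r_by_session=np.zeros((0, len(t))),
                                zero_variance=np.zeros(len(t), dtype=bool))
    report.p = t["p"].to_numpy()
    report.q = t["q"].to_numpy()
    report.ceiling = t["ceiling"].to_numpy()
    report.assigned_layer = t["assigned_layer"].to_numpy(dtype=int)
    report.layer_r2 = ncio.read_matrix(d / "layer_r2.tsv")
    ctx.update(report=report, test_proc=test)


def _stage_catmap(cfg: PipelineConfig, d: Path, ctx: dict):
    atlas = cm.build_maps(ctx["model"], ctx["bases"], ctx["atlas"], ctx["standardizers"])
    resp_by_cat = cm.exemplar_responses(ctx["model"], ctx["bases"], ctx["atlas"],
                                        ctx["standardizers"])
    profile = cm.dprime(resp_by_cat, categories=atlas.categories)
    ctx.update(atlas=atlas, exemplar_resp=resp_by_cat, selectivity=profile)
    ncio.write_labeled_matrix(d / "category_maps.tsv", atlas.maps,
                              atlas.categories)
    dmat = pd.DataFrame(profile.dprime_by_category, columns=atlas.categories)
    dmat.insert(0, "selectivity", profile.selectivity)
    dmat.to_csv(d / "selectivity.tsv", sep="\t", index_label="voxel",
                float_format="%.17g")
    return _stage_outputs(d, ["category_maps.tsv", "selectivity.tsv"])


def _load_catmap(cfg: PipelineConfig, d: Path, ctx: dict):
    maps, cats = ncio.read_labeled_matrix(d / "category_maps.tsv")
    ctx["atlas"] = cm.CategoryAtlas(categories=cats,
                                    exemplar_features=ctx["atlas"].exemplar_features,
                                    exemplar_counts=ctx["atlas"].exemplar_counts,
                                    maps=maps)
    ctx["exemplar_resp"] = cm.exemplar_responses(ctx["model"], ctx["bases"],
                                                 ctx["atlas"], ctx["standardizers"])


def _stage_cluster(cfg: PipelineConfig, d: Path, ctx: dict):
    mask = cl.predictable_mask(ctx["report"], cfg.thresholds["q"], cfg.thresholds["r"])
    net = cl.similarity_matrix(ctx["atlas"].maps, mask, ctx["atlas"].categories,
                               mask_id="predictable")
    kmin, kmax = cfg.k_range
    result = cl.cluster_categories(net, k_range=range(kmin, kmax + 1),
                                   n_restarts=cfg.n_restarts, seed=cfg.seed)
    result.p_perm = cl.modularity_permutation_test(
        net, result.labels, n_perm=cfg.permutations["modularity"], seed=cfg.seed)
    ctx.update(mask=mask, net=net, clustering=result)
    ncio.write_matrix(d / "predictable_mask.tsv", mask.astype(int))
    ncio.write_labeled_matrix(d / "similarity.tsv", net.S, net.labels)
    ncio.write_json(d / "clustering.json", {
        "labels": result.labels.tolist(), "k": result.k, "Q": result.Q,
        "Q_plus": result.Q_plus, "Q_minus": result.Q_minus,
        "k_scan": [[int(k), float(q)] for k, q in result.k_scan],
        "p_perm": result.p_perm, "unstable": bool(result.unstable)})
    return _stage_outputs(d, ["predictable_mask.tsv", "similarity.tsv", "clustering.json"])


def _load_cluster(cfg: PipelineConfig, d: Path, ctx: dict):
    ctx["mask"] = ncio.read_matrix(d / "predictable_mask.tsv").ravel().astype(bool)
    s, labels = ncio.read_labeled_matrix(d / "similarity.tsv")
    ctx["net"] = cl.SimilarityNetwork(S=s, labels=labels, mask_id="predictable")
    cj = ncio.read_json(d / "clustering.json")
    ctx["clustering"] = cl.ClusteringResult(
        labels=np.array(cj["labels"]), k=cj["k"], Q=cj["Q"], Q_plus=cj["Q_plus"],
        Q_minus=cj["Q_minus"], k_scan=[tuple(x) for x in cj["k_scan"]],
        p_perm=cj["p_perm"], unstable=cj["unstable"])


def _stage_semantics(cfg: PipelineConfig, d: Path, ctx: dict):
    cats = ctx["atlas"].categories
    lch = sem.semantic_matrix(cats, "lch", ctx["taxonomy"])
    cos = sem.semantic_matrix(cats, "vector_cosine", ctx["vectors"])
    n_perm = cfg.permutations["semantic"]
    results = {}
    for name, mat in (("lch", lch), ("cosine", cos)):
        r, p = sem.representational_semantic_correlation(ctx["net"].S, mat,
                                                         n_perm=n_perm, seed=cfg.seed)
        results[name] = {"r": r, "p": p, "n_perm": n_perm, "seed": cfg.seed}
    ctx.update(sem_lch=lch, sem_cosine=cos, sem_results=results)
    ncio.write_labeled_matrix(d / "semantic_lch.tsv", lch.matrix, cats)
    ncio.write_labeled_matrix(d / "semantic_cosine.tsv", cos.matrix, cats)
    ncio.write_json(d / "semantic_correlation.json", results)
    return _stage_outputs(d, ["semantic_lch.tsv", "semantic_cosine.tsv",
                              "semantic_correlation.json"])


def _load_semantics(cfg: PipelineConfig, d: Path, ctx: dict):
    cats = ctx["atlas"].categories
    m1, _ = ncio.read_labeled_matrix(d / "semantic_lch.tsv")
    m2, _ = ncio.read_labeled_matrix(d / "semantic_cosine.tsv")
    ctx["sem_lch"] = sem.SemanticSimilarity(matrix=m1, labels=cats, method="lch")
    ctx["sem_cosine"] = sem.SemanticSimilarity(matrix=m2, labels=cats,
                                               method="vector_cosine")
    ctx["sem_results"] = ncio.read_json(d / "semantic_correlation.json")


def _stage_layers(cfg: PipelineConfig, d: Path, ctx: dict):
    profile = ly.layer_profile(
        ctx["model"], ctx["bases"], ctx["atlas"], ctx["standardizers"], ctx["mask"],
        ctx["clustering"].labels,
        semantic_sources={"lch": ctx["sem_lch"].matrix,
                          "cosine": ctx["sem_cosine"].matrix},
        n_perm=cfg.permutations["semantic"], seed=cfg.seed)
    ctx["layer_profile"] = profile
    profile.to_frame().to_csv(d / "layer_profile.tsv", sep="\t", index=False,
                              float_format="%.17g")
    ncio.write_json(d / "layer_profile.json", {
        "argmax_Q_layer": profile.argmax_Q_layer,
        "argmax_r_layer": profile.argmax_r_layer})
    return _stage_outputs(d, ["layer_profile.tsv", "layer_profile.json"])


_RUNNERS = {"synth": (_stage_synth, _load_synth),
            "features": (_stage_features, _load_features),
            "encode": (_stage_encode, _load_encode),
            "catmap": (_stage_catmap, _load_catmap),
            "cluster": (_stage_cluster, _load_cluster),
            "semantics": (_stage_semantics, _load_semantics),
            "layers": (_stage_layers, None)}


def run_pipeline(config: PipelineConfig, out_dir, resume: bool = False,
                 stop_after: str | None = None, context: dict | None = None) -> RunManifest:
    """Execute all stages (or resume, skipping stages whose outputs and
    manifest entries already exist). A stage failure raises with the stage
    name attached; earlier outputs are preserved on disk. Pass a dict as
    ``context`` to receive the in-memory stage artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    prior = {}
    if resume and manifest_path.exists():
        for s in ncio.read_json(manifest_path)["stages"]:
            prior[s["stage"]] = s
    manifest = RunManifest()
    ctx: dict = context if context is not None else {}
    for name in STAGES:
        run, load = _RUNNERS[name]
        d = out / name
        done = (name in prior
                and all((d / f).exists() and _sha256(d / f) == h
                        for f, h in prior[name]["outputs"].items()))
        t0 = time.monotonic()
        if done and load is not None:
            load(config, d, ctx)
            manifest.stages.append(prior[name])
        elif done and load is None:
            manifest.stages.append(prior[name])
        else:
            d.mkdir(parents=True, exist_ok=True)
            try:
                outputs = run(config, d, ctx)
            except Exception as e:
                raise RuntimeError(f"stage '{name}' failed: {e}") from e
            manifest.add(name, outputs, config.seed, time.monotonic() - t0)
        ncio.write_json(manifest_path, {"stages": manifest.stages})
        if stop_after == name:
            break
    return manifest
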