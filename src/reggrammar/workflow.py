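"""End-to-end orchestration of the synthetic analysis pipeline.

`run_pipeline` executes generate -> expression -> features -> train ->
relevance -> motifs -> rules -> swap -> coevolution on a synthetic
cohort, writing per-stage outputs plus a JSON manifest (config hash,
derived seeds, metrics, file checksums). One global seed fans out to
per-stage seeds through `numpy.random.SeedSequence.spawn`, so any stage
can be re-run in isolation with its recorded seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import coevolution, expression, motifs, relevance, rules, swap, synth
from . import models as mdl
from .features import RegionLengths, bundle_features

STAGES = ("simulate", "expr", "features", "train", "relevance", "motifs",
          "rules", "swap", "coevo")


@dataclass
class PipelineConfig:
    """All pipeline thresholds in one serializable object.

    Defaults: TPM filter 5, RSD filter 1, 80/10/10 split, 10-bp
    occlusion windows at a +/-2 SD cutoff, motif identity 0.8 with
    minimum cluster size 5 and 0.2-bit trimming, rules with >= 3 carrier
    genes at FDR 0.05 and up to 6 motifs.
    """

    generator: synth.GeneratorConfig = field(default_factory=synth.GeneratorConfig)
    n_experiments: int = 100
    min_tpm: float = 5.0
    rsd_max: float = 1.0
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    model: mdl.ModelSpec = field(default_factory=mdl.ModelSpec.scaled)
    relevance_window: int = 10
    relevance_cutoff_sd: float = 2.0
    relevance_genes: int = 400  # genes profiled for motif discovery
    attribution_models: int = 2  # ensemble size for reproducible masks
    motif_identity: float = 0.8
    motif_min_cluster: int = 5
    motif_trim_bits: float = 0.2
    rules_min_genes: int = 3
    rules_alpha: float = 0.05
    rules_max_size: int = 6
    swap_genes: int = 60
    coevo_species: int = 8
    coevo_correlation: float = 0.45
    coevo_cutoff: float = 0.2
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_as_plain(dataclasses.asdict(self))))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        gen = raw.pop("generator", {})
        lengths = gen.pop("region_lengths", None)
        if lengths:
            gen["region_lengths"] = RegionLengths(**lengths)
        if "effect_range" in gen:
            gen["effect_range"] = tuple(gen["effect_range"])
        if "rule_size_probs" in gen:
            gen["rule_size_probs"] = {int(k): v for k, v in gen["rule_size_probs"].items()}
        model = raw.pop("model", {})
        blocks = [mdl.ConvBlock(**b) for b in model.pop("conv_blocks", [])]
        if "fc_layers" in model:
            model["fc_layers"] = tuple(model["fc_layers"])
        spec = mdl.ModelSpec(conv_blocks=blocks, **model) if blocks else mdl.ModelSpec(**model)
        if "split_fractions" in raw:
            raw["split_fractions"] = tuple(raw["split_fractions"])
        return cls(generator=synth.GeneratorConfig(**gen), model=spec, **raw)

    @classmethod
    def demo(cls) -> "PipelineConfig":
        """Small configuration for the one-command synthetic demo."""
        cfg = cls()
        cfg.generator = synth.GeneratorConfig(n_genes=800, n_motifs=12, n_rules=20)
        cfg.n_experiments = 50
        cfg.model = mdl.ModelSpec.scaled()
        cfg.model.warmup_epochs = 25
        cfg.model.epochs = 45
        cfg.relevance_genes = 120
        cfg.swap_genes = 30
        cfg.rules_max_size = 3
        return cfg


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds below 2**31 from one global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(STAGES, children)}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 mode: str = "synthetic",
                 counts_path: str | Path | None = None) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    Real mode consumes an external counts matrix; synthetic mode needs
    no inputs. Failures halt with the stage name; outputs written so far
    remain on disk alongside a partial manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    cfg_yaml = outdir / "config.yaml"
    config.to_yaml(cfg_yaml)
    manifest: dict = {
        "config_hash": _checksum(cfg_yaml),
        "seeds": seeds,
        "stages": {},
        "files": {},
    }

    def _fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(_as_plain(manifest), indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    def _record(stage: str, t0: float, **metrics):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2),
                                     **_as_plain(metrics)}

    lengths = config.generator.region_lengths

    # simulate ------------------------------------------------------------
    t0 = time.time()
    try:
        if mode == "synthetic":
            genes, truth = synth.generate_genome(config.generator, seeds["simulate"])
            expr = synth.generate_expression(genes, truth, config.n_experiments,
                                             seeds["expr"], config.generator)
            cohort = synth.SyntheticCohort(genes, expr, truth, config.seed)
            paths = synth.write_cohort(cohort, outdir / "cohort")
            manifest["files"].update(paths)
        else:
            if counts_path is None or not Path(counts_path).exists():
                raise FileNotFoundError(f"counts file not found: {counts_path}")
            raise NotImplementedError("real mode requires external sequence inputs")
    except Exception as exc:  # noqa: BLE001
        _fail("expr" if mode == "real" else "simulate", exc)
    _record("simulate", t0, n_genes=len(genes), n_rules=len(truth.planted_rules))

    # expr ----------------------------------------------------------------
    t0 = time.time()
    try:
        kept, summaries = expression.filter_genes(expr, config.min_tpm, config.rsd_max)
        gene_map = {g.gene_id: g for g in genes}
        kept_genes = [gene_map[g] for g in kept]
        orf_lengths = np.array([len(g.regions["cds"]) for g in kept_genes], float)
        split = mdl.SplitPlan.make(kept, config.split_fractions, seeds["train"])
        fit_mask = np.isin(kept, split.train)
        targets, transform = expression.median_target(summaries, orf_lengths,
                                                      fit_mask=fit_mask)
        vr = expression.variance_ratio(expr)
    except Exception as exc:  # noqa: BLE001
        _fail("expr", exc)
    _record("expr", t0, n_kept=len(kept),
            median_variance_ratio=float(np.median(vr["ratio"].replace(np.inf, np.nan).dropna())),
            boxcox_lambda=transform.lmbda)

    # features ------------------------------------------------------------
    t0 = time.time()
    try:
        bundles = {g.gene_id: bundle_features(g.gene_id, g.regions, lengths)
                   for g in kept_genes}
        x_seq = np.stack([bundles[g].concat_onehot() for g in kept])
        x_num = np.stack([bundles[g].numeric for g in kept])
    except Exception as exc:  # noqa: BLE001
        _fail("features", exc)
    _record("features", t0, seq_shape=list(x_seq.shape))

    # train ---------------------------------------------------------------
    t0 = time.time()
    try:
        spec = dataclasses.replace(config.model, seed=seeds["train"])
        model = mdl.build_model(spec, x_seq.shape[1:], x_num.shape[1])
        model, history = mdl.train(model, x_seq, x_num, targets, split, kept)
        idx = split.indices(kept)
        report = mdl.evaluate(model.predict(x_seq[idx["test"]], x_num[idx["test"]]),
                              targets[idx["test"]])
    except Exception as exc:  # noqa: BLE001
        _fail("train", exc)
    _record("train", t0, test_r2=report.r_squared, test_mse=report.mse,
            epochs_run=len(history))

    # relevance -----------------------------------------------------------
    t0 = time.time()
    try:
        rng = np.random.default_rng(seeds["relevance"])
        n_prof = min(config.relevance_genes, len(kept))
        prof_idx = rng.choice(len(kept), size=n_prof, replace=False)
        # relevance ratios are taken on the positive pre-length-correction
        # Box-Cox scale: shift each gene's prediction by its length term
        y_offsets = transform.intercept + transform.slope * np.log10(orf_lengths)
        views = [model.sequence_model() if model.warmup_weights else model]
        if model.warmup_weights is not None:
            for k in range(1, config.attribution_models):
                sp = dataclasses.replace(config.model,
                                         seed=seeds["relevance"] + k)
                sp.epochs = sp.warmup_epochs  # sequence phase only
                extra = mdl.build_model(sp, x_seq.shape[1:], x_num.shape[1])
                extra, _ = mdl.train(extra, x_seq, x_num, targets, split, kept)
                views.append(extra.sequence_model())
        profile_sets = [
            [relevance.relevance_profile(v, x_seq[i], x_num[i], kept[i],
                                         lengths, config.relevance_window,
                                         y_offset=float(y_offsets[i]))
             for i in prof_idx]
            for v in views
        ]
        masks, candidate = relevance.ensemble_masks(
            profile_sets, config.relevance_cutoff_sd)
        profiles = relevance.average_profiles(profile_sets)
    except Exception as exc:  # noqa: BLE001
        _fail("relevance", exc)
    _record("relevance", t0, n_profiles=len(profiles),
            n_attribution_models=len(views),
            mean_significant_bp=float(np.mean(
                [m.sum() for gm in masks.values() for m in gm.values()])))

    # motifs --------------------------------------------------------------
    t0 = time.time()
    try:
        seqs = {g.gene_id: g.regions for g in kept_genes}
        windows = motifs.extract_windows(profiles, candidate, seqs,
                                         config.relevance_window)
        found = motifs.cluster_to_motifs(windows, config.motif_identity,
                                         config.motif_min_cluster,
                                         config.motif_trim_bits)
        motifs.write_meme(found, outdir / "motifs.meme")
        manifest["files"]["motifs"] = str(outdir / "motifs.meme")
    except Exception as exc:  # noqa: BLE001
        _fail("motifs", exc)
    _record("motifs", t0, n_windows=len(windows), n_motifs=len(found))

    # rules ---------------------------------------------------------------
    t0 = time.time()
    try:
        median_tpm = expr.to_frame().loc[kept].median(axis=1)
        occ = truth_occurrence(kept_genes, truth)
        sig, stats = rules.mine_rules(occ, median_tpm,
                                      min_genes=config.rules_min_genes,
                                      max_size=config.rules_max_size,
                                      alpha=config.rules_alpha)
        rules_to_tsv(sig, outdir / "rules.tsv")
        manifest["files"]["rules"] = str(outdir / "rules.tsv")
    except Exception as exc:  # noqa: BLE001
        _fail("rules", exc)
    _record("rules", t0, **stats)

    # swap ----------------------------------------------------------------
    t0 = time.time()
    try:
        sub = kept_genes[: config.swap_genes]
        orf_map = {g.gene_id: len(g.regions["cds"]) for g in sub}
        stream, count = swap.enumerate_combinations(sub)
        preds = swap.predict_constructs(model, stream, bundles, orf_map,
                                        transform, lengths)
    except Exception as exc:  # noqa: BLE001
        _fail("swap", exc)
    _record("swap", t0, n_constructs=count,
            max_fold=float(preds.fold_change.max()),
            min_fold=float(preds.fold_change.min()))

    # coevo ---------------------------------------------------------------
    t0 = time.time()
    try:
        alns, true_rates = synth.generate_orthologs(
            kept_genes, config.coevo_species, config.coevo_correlation,
            seeds["coevo"])
        est = coevolution.rates_table(alns, config.coevo_cutoff)
        r, p, n_used = coevolution.correlate_regions(est, "promoter", "cds")
    except Exception as exc:  # noqa: BLE001
        _fail("coevo", exc)
    _record("coevo", t0, pearson_r=r, p_value=p, n=n_used)

    for name, path in list(manifest["files"].items()):
        manifest["files"][name] = {"path": path, "sha256": _checksum(Path(path))}
    (outdir / "manifest.json").write_text(json.dumps(_as_plain(manifest), indent=1))
    return manifest


def truth_occurrence(genes: list[synth.GeneRecord], truth: synth.GrammarTruth):
    """Ground-truth gene x motif presence matrix from planted positions."""
    import pandas as pd

    ids = [m.motif_id for m in truth.planted_motifs]
    data = {m: [g.carries(m) for g in genes] for m in ids}
    return pd.DataFrame(data, index=[g.gene_id for g in genes])


def rules_to_tsv(sig: list[rules.Rule], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "motifs": "+".join(sorted(r.motif_ids)),
            "n_genes": len(r.genes),
            "support": r.support,
            "confidence": r.confidence,
            "lift": r.lift,
            "chi2": r.chi2,
            "p": r.p_value,
            "q": r.q_value,
            "mean_tpm": r.mean_tpm,
            "snr": r.snr,
        }
        for r in sig
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
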