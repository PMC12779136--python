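"""End-to-end orchestration: preprocess -> GAN augmentation -> per-sample
context models + FBA -> biological filtration -> class balancing -> flux
features -> random forest -> multi-level importance, with deterministic
per-stage seeding and a checksummed run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_data as synth
from .classify import RFConfig, assemble_features, train_rf
from .contextualize import (
    DiscretizationConfig,
    IMATConfig,
    InfeasibleModelError,
    contextualize_sample,
)
from .core_model import read_metabolic_model
from .expression import (
    CANCER,
    HEALTHY,
    ExpressionMatrix,
    filter_zero_genes,
    read_expression_matrix,
)
from .filtration import GDIConfig, reports_to_rows, run_filtration
from .gan_augment import GANConfig, sample_synthetic, train_wgan_gp
from .importance import ImportanceConfig, build_ledger, cluster_reactions, flux_activity_summary

log = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    # inputs: either file paths or the built-in toy study
    expression_path: str | None = None
    labels_path: str | None = None
    network_path: str | None = None
    network_format: str = "json"
    toy: bool = True
    phenotype: synth.PhenotypeSpec = field(default_factory=synth.imbalanced_phenotype_spec)
    minority_label: str = HEALTHY

    gan: GANConfig = field(default_factory=GANConfig)
    n_synthetic: int = 251
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    imat: IMATConfig = field(default_factory=IMATConfig)
    gdi: GDIConfig | None = None  # toy default filled in at run time
    gluconeogenesis_markers: list[str] = field(
        default_factory=lambda: [synth.GLUCONEOGENESIS_MARKER]
    )
    rf: RFConfig = field(default_factory=RFConfig)
    importance: ImportanceConfig = field(default_factory=ImportanceConfig)
    family_map: dict[str, str] = field(default_factory=synth.toy_gene_families)
    seed: int = 0
    outdir: str = "fluxgan_run"

    def __post_init__(self) -> None:
        if self.n_synthetic < 1:
            raise ValueError("n_synthetic must be >= 1")

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        kwargs = dict(doc)
        if "phenotype" in kwargs:
            kwargs["phenotype"] = synth.PhenotypeSpec(
                **{
                    k: (frozenset(v) if k.startswith("planted") else v)
                    for k, v in kwargs["phenotype"].items()
                }
            )
        for key, klass in (
            ("gan", GANConfig),
            ("discretization", DiscretizationConfig),
            ("imat", IMATConfig),
            ("rf", RFConfig),
            ("importance", ImportanceConfig),
        ):
            if key in kwargs:
                kwargs[key] = klass(**kwargs[key])
        if "gdi" in kwargs and kwargs["gdi"] is not None:
            kwargs["gdi"] = GDIConfig(**kwargs["gdi"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def balance_report(
    real_minority_ids: list[str],
    qualified_ids: list[str],
    n_majority: int,
    seed: int = 0,
) -> dict:
    """Counts plus the seeded subsample of qualified synthetic samples that
    brings the minority total to exactly the majority count (when possible)."""
    needed = n_majority - len(real_minority_ids)
    rng = np.random.default_rng(seed)
    if len(qualified_ids) >= needed:
        chosen = sorted(rng.choice(qualified_ids, size=max(needed, 0), replace=False))
        balanced = True
    else:
        chosen = list(qualified_ids)
        balanced = False
        log.warning(
            "insufficient qualified synthetic samples (%d < %d): proceeding unbalanced",
            len(qualified_ids),
            needed,
        )
    return {
        "n_real_minority": len(real_minority_ids),
        "n_qualified": len(qualified_ids),
        "n_majority": n_majority,
        "n_selected_synthetic": len(chosen),
        "balanced": balanced,
        "selected": list(chosen),
    }


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage, write artifacts under cfg.outdir, and return the
    in-memory results (reports, ledger, manifest)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- stage 0: inputs -------------------------------------------------
    if cfg.toy:
        net = synth.build_toy_network()
        pheno = synth.PhenotypeSpec(
            **{**_spec_dict(cfg.phenotype), "seed": stage_seed(cfg.seed, "simulate")}
        )
        expr = synth.simulate_expression(net, pheno)
    else:
        net = read_metabolic_model(cfg.network_path, format=cfg.network_format)
        expr = read_expression_matrix(cfg.expression_path, cfg.labels_path)
    expr = filter_zero_genes(expr)
    gdi_cfg = cfg.gdi or GDIConfig(
        lactate_exchange_id=synth.LACTATE_EXCHANGE,
        glucose_exchange_id=synth.GLUCOSE_EXCHANGE,
    )
    log.info("inputs: %d genes x %d samples, %d reactions", *expr.shape, len(net.reactions))

    labels = dict(expr.labels)
    minority = cfg.minority_label
    majority = CANCER if minority == HEALTHY else HEALTHY
    minority_ids = [s for s in expr.sample_ids if labels[s] == minority]
    majority_ids = [s for s in expr.sample_ids if labels[s] == majority]

    # ---- stage 1: GAN augmentation (only when the classes are imbalanced) -
    synthetic_expr = None
    history = None
    if len(minority_ids) < len(majority_ids):
        gan_cfg = GANConfig(
            **{**asdict_config(cfg.gan), "seed": stage_seed(cfg.seed, "gan")}
        )
        minority_expr = expr.restrict_to_label(minority)
        bundle, scaler, history = train_wgan_gp(minority_expr, gan_cfg)
        synthetic_expr = sample_synthetic(
            bundle, scaler, cfg.n_synthetic, seed=stage_seed(cfg.seed, "sample")
        )
        history.to_csv(out / "gan_loss_history.csv", index=False)
        log.info("GAN: generated %d synthetic %s profiles", cfg.n_synthetic, minority)

    # ---- stage 2: contextualize + FBA ------------------------------------
    def _contextualize(matrix: ExpressionMatrix, ids: list[str]) -> dict:
        results = {}
        for s in ids:
            try:
                results[s] = contextualize_sample(
                    matrix, net, s, cfg.discretization, cfg.imat
                )
            except InfeasibleModelError as exc:  # excluded downstream
                log.warning("sample %s excluded: %s", s, exc)
        return results

    real_models = _contextualize(expr, expr.sample_ids)
    synth_models = (
        _contextualize(synthetic_expr, synthetic_expr.sample_ids)
        if synthetic_expr is not None
        else {}
    )

    # ---- stage 3: filtration + balancing ---------------------------------
    real_minority_profiles = [
        fp for s, (_, fp) in real_models.items() if labels[s] == minority
    ]
    reports = []
    balance = None
    selected_synth: list[str] = []
    if synth_models:
        candidates = [fp for _, fp in synth_models.values()]
        survivors, reports = run_filtration(
            candidates,
            real_minority_profiles,
            net,
            gdi_cfg,
            cfg.gluconeogenesis_markers,
        )
        qualified = sorted(fp.sample_id for fp in survivors)
        balance = balance_report(
            [s for s in minority_ids if s in real_models],
            qualified,
            n_majority=len([s for s in majority_ids if s in real_models]),
            seed=stage_seed(cfg.seed, "balance"),
        )
        selected_synth = balance["selected"]
        pd.DataFrame(reports_to_rows(reports)).to_csv(
            out / "filter_report.tsv", sep="\t", index=False
        )
        with open(out / "balance.json", "w") as fh:
            json.dump(balance, fh, indent=1, sort_keys=True)
            fh.write("\n")

    # ---- stage 4: features + forest --------------------------------------
    models = [real_models[s] for s in expr.sample_ids if s in real_models]
    all_labels = dict(labels)
    all_origin = dict(expr.origin)
    for s in selected_synth:
        models.append(synth_models[s])
        all_labels[s] = minority
        all_origin[s] = "synthetic"
    fm = assemble_features(models, all_labels, all_origin)
    fm.values.to_csv(out / "features.tsv", sep="\t", index_label="sample_id",
                     float_format="%.10g")
    with open(out / "feature_labels.tsv", "w") as fh:
        for s in fm.sample_ids:
            fh.write(f"{s}\t{fm.labels[s]}\n")
    rf_cfg = RFConfig(**{**asdict_config(cfg.rf), "seed": stage_seed(cfg.seed, "rf")})
    model, clf_report = train_rf(fm, rf_cfg)
    with open(out / "classifier_report.json", "w") as fh:
        json.dump(clf_report.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    log.info(
        "forest: accuracy %.4f, recall(%s) %.3f",
        clf_report.accuracy,
        CANCER,
        clf_report.per_class[CANCER]["recall"],
    )

    # ---- stage 5: importance ---------------------------------------------
    ledger = build_ledger(model, fm, net, cfg.importance, cfg.family_map)
    subsystem = {r.id: (r.subsystem or "Unassigned") for r in net.reactions}
    imp_df = pd.DataFrame(
        {
            "reaction_id": list(ledger.reaction_importance),
            "importance": list(ledger.reaction_importance.values()),
            "spearman_rho": [ledger.spearman_rho[r] for r in ledger.reaction_importance],
            "subsystem": [subsystem.get(r, "Unassigned") for r in ledger.reaction_importance],
        }
    ).sort_values("importance", ascending=False)
    imp_df.to_csv(out / "importance.tsv", sep="\t", index=False, float_format="%.10g")

    pw_df = pd.DataFrame(
        [(p, m, s) for p, (m, s) in ledger.pathway.items()],
        columns=["pathway", "mean_importance", "share_pct"],
    ).sort_values("share_pct", ascending=False)
    pw_df.to_csv(out / "pathways.tsv", sep="\t", index=False, float_format="%.10g")

    fam_df = pd.DataFrame(
        [
            (f, s, ledger.family_tiers.get(f, ""))
            for f, s in sorted(ledger.family_scores.items(), key=lambda kv: -kv[1])
        ],
        columns=["family", "score", "tier"],
    )
    fam_df.to_csv(out / "gene_families.tsv", sep="\t", index=False, float_format="%.10g")

    top_n = min(cfg.importance.cluster_top_n, len(fm.feature_ids))
    _, leaves, newick = cluster_reactions(fm, ledger.reaction_importance, top_n)
    (out / "reaction_tree.nwk").write_text(newick + "\n")

    top_reaction = imp_df.iloc[0]["reaction_id"]
    activity = flux_activity_summary(fm, top_reaction, cfg.importance)
    act_rows = []
    for label, series in activity.items():
        for s, rm, ar in zip(
            series["samples"], series["rolling_mean"], series["activity_ratio"]
        ):
            act_rows.append((top_reaction, label, s, rm, ar))
    pd.DataFrame(
        act_rows,
        columns=["reaction_id", "label", "sample_id", "rolling_mean", "activity_ratio"],
    ).to_csv(out / "activity.tsv", sep="\t", index=False, float_format="%.10g")

    # ---- manifest ---------------------------------------------------------
    artifacts = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": cfg.seed,
        "stage_seeds": {
            s: stage_seed(cfg.seed, s) for s in ("simulate", "gan", "sample", "balance", "rf")
        },
        "config_hash": hashlib.sha256(
            json.dumps(_config_fingerprint(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "files": {name: _sha256_file(out / name) for name in artifacts},
        "counts": {
            "n_samples_real": len(real_models),
            "n_synthetic_generated": len(synth_models),
            "n_synthetic_selected": len(selected_synth),
            "n_features": len(fm.feature_ids),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return {
        "network": net,
        "features": fm,
        "classifier_report": clf_report,
        "ledger": ledger,
        "filter_reports": reports,
        "balance": balance,
        "manifest": manifest,
        "gan_history": history,
        "top_reaction": top_reaction,
    }


def _spec_dict(spec) -> dict:
    d = asdict(spec)
    for k in ("planted_up_genes", "planted_down_genes"):
        d[k] = frozenset(d[k])
    return d


def asdict_config(cfg) -> dict:
    return asdict(cfg)


def _config_fingerprint(cfg: PipelineConfig) -> dict:
    doc = asdict(cfg)
    for key in ("phenotype",):
        for k in ("planted_up_genes", "planted_down_genes"):
            doc[key][k] = sorted(doc[key][k])
    return doc
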