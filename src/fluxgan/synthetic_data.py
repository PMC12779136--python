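"""Desk-scale study system: a toy metabolic network and expression simulator.

The toy network is a ~30-reaction surrogate for a genome-scale human model.
It covers the functional territory the pipeline exercises: glucose uptake,
lumped glycolysis / pentose-phosphate / TCA / oxidative phosphorylation
producing the currency metabolites (ATP, NADH, NADPH), lactate dehydrogenase
with a lactate exchange (so Warburg-like secretion is expressible), an
ATP-consuming gluconeogenesis marker reaction, a three-step lysosomal
heparan-sulfate degradation chain, and an extracellular->cytosol fatty-acid
transport/activation branch carrying multi-gene (isozyme) GPRs.

The expression simulator is log-normal per gene: FPKM-like values
``2**(baseline_g + class_shift + N(0, noise_sd))`` where the class shift
plants up-/down-regulated gene sets in the cancer class.  It targets only
the statistical structure the pipeline assumes (non-negative skewed values,
class-dependent mean shifts, independent noise), not real covariance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import MetabolicNetwork, Metabolite, Reaction
from .expression import CANCER, HEALTHY, REAL, ExpressionMatrix, write_expression_matrix
from .gpr import parse_gpr

#: genes planted as up-regulated in the cancer class by default: the
#: fatty-acid transport/activation branch (FABP / SLC27A / ACSL / ACSBG
#: analogs).
DEFAULT_PLANTED_UP = frozenset(
    {"FABP1", "FABP2", "FABP4", "SLC27A1", "ACSL1", "ACSL3", "ACSBG1"}
)
#: genes planted as down-regulated in cancer: the lysosomal heparan-sulfate
#: degradation chain.
DEFAULT_PLANTED_DOWN = frozenset({"SGSH", "NAGLU", "GNS"})

SUBSYSTEM_TRANSPORT = "Transport reactions"
SUBSYSTEM_HS_DEG = "Heparan sulfate degradation"
SUBSYSTEM_FA_ACT = "Fatty acid activation"
SUBSYSTEM_EXCHANGE = "Exchange/demand reactions"
GLUCONEOGENESIS_MARKER = "GNG"
GLUCOSE_EXCHANGE = "EX_glc"
LACTATE_EXCHANGE = "EX_lac"


@dataclass(frozen=True)
class ToyNetworkSpec:
    include_gluconeogenesis_marker: bool = True
    include_lysosomal_branch: bool = True
    include_fatty_acid_branch: bool = True
    flux_cap: float = 1000.0

    def __post_init__(self) -> None:
        if self.flux_cap <= 0:
            raise ValueError("flux_cap must be positive")


@dataclass(frozen=True)
class PhenotypeSpec:
    """Cohort structure for the two-phenotype expression simulator."""

    n_healthy: int = 40
    n_cancer: int = 40
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 0.5
    planted_up_genes: frozenset[str] = DEFAULT_PLANTED_UP
    planted_down_genes: frozenset[str] = DEFAULT_PLANTED_DOWN
    effect_size: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 1 or self.n_cancer < 1:
            raise ValueError("sample counts must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if set(self.planted_up_genes) & set(self.planted_down_genes):
            raise ValueError("planted up/down gene sets must be disjoint")


def imbalanced_phenotype_spec(seed: int = 0) -> PhenotypeSpec:
    """Cohort preset mirroring a severe minority-class imbalance (40 cancer
    vs 4 healthy, a 10:1 ratio comparable to the 144:4 study design)."""
    return PhenotypeSpec(n_healthy=4, n_cancer=40, seed=seed)


def build_toy_network(spec: ToyNetworkSpec = ToyNetworkSpec()) -> MetabolicNetwork:
    """Construct the toy network; flux-consistent (biomass optimum > 0).

    Biomass consumes ATP, pyruvate and NADPH plus two branch-fed precursors:
    acyl-CoA (imported fatty acid via transport + activation, or de novo
    synthesis) and a glycan precursor (lysosomal heparan-sulfate salvage, or
    de novo synthesis).  The de novo routes carry no GPR, so expression can
    switch the cheap branch routes off without making biomass infeasible.
    Mass tags are lumped conservation units (a coarse carbon count), checked
    by the balance tests for every internal reaction.
    """
    cap = spec.flux_cap

    mets = [
        Metabolite("glc_e", "glucose", "e", 6),
        Metabolite("glc_c", "glucose", "c", 6),
        Metabolite("g6p_c", "glucose-6-phosphate", "c", 6),
        Metabolite("pyr_c", "pyruvate", "c", 3),
        Metabolite("lac_c", "lactate", "c", 3),
        Metabolite("lac_e", "lactate", "e", 3),
        Metabolite("co2_c", "CO2", "c", 1),
        Metabolite("atp_c", "ATP", "c", 0),
        Metabolite("nadh_c", "NADH", "c", 0),
        Metabolite("nadph_c", "NADPH", "c", 0),
        Metabolite("facoa_c", "acyl-CoA", "c", 6),
        Metabolite("gag_c", "glycan precursor", "c", 6),
        Metabolite("gp1_c", "core 1 O-glycan intermediate", "c", 6),
        Metabolite("gp2_c", "core 2 O-glycan intermediate", "c", 6),
        Metabolite("glycoprot_c", "glycoprotein", "c", 6),
        Metabolite("biomass_c", "biomass", "c", 12),
        Metabolite("aa_e", "amino acid pool", "e", 3),
        Metabolite("aa_c", "amino acid pool", "c", 3),
    ]

    def rxn(rid, stoich, lb, ub, subsystem, gpr="", exch=False):
        return Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            subsystem=subsystem,
            gpr=parse_gpr(gpr),
            is_exchange=exch,
        )

    rxns = [
        rxn(GLUCOSE_EXCHANGE, {"glc_e": -1}, -10, 0, SUBSYSTEM_EXCHANGE, exch=True),
        rxn(
            "GLCt",
            {"glc_e": -1, "glc_c": 1},
            0,
            cap,
            SUBSYSTEM_TRANSPORT,
            "SLC2A1 or SLC2A2 or SLC2A3",
        ),
        rxn(
            "HEX",
            {"glc_c": -1, "atp_c": -1, "g6p_c": 1},
            0,
            cap,
            "Glycolysis",
            "HK1 or HK2 or HK3",
        ),
        rxn(
            "GLYC",
            {"g6p_c": -1, "pyr_c": 2, "atp_c": 3, "nadh_c": 2},
            0,
            cap,
            "Glycolysis",
            "GAPDH or PGK1 or PKM",
        ),
        rxn(
            "PPP",
            {"g6p_c": -1, "pyr_c": 1, "co2_c": 3, "nadph_c": 2},
            0,
            cap,
            "Pentose phosphate pathway",
            "G6PD or PGD or TKT",
        ),
        rxn(
            "TCA",
            {"pyr_c": -1, "co2_c": 3, "atp_c": 10, "nadh_c": 4},
            0,
            cap,
            "TCA cycle",
            "CS and SDHA",
        ),
        rxn(
            "OXPHOS",
            {"nadh_c": -1, "atp_c": 2},
            0,
            cap,
            "Oxidative phosphorylation",
            "NDUFA1 or SDHB or COX4I1",
        ),
        # transhydrogenase-like NADPH fallback; no gene evidence attached
        rxn("THD", {"nadh_c": -1, "atp_c": -1, "nadph_c": 1}, 0, cap, "Oxidative phosphorylation"),
        # non-growth-associated ATP maintenance, constant in every context
        rxn("ATPM", {"atp_c": -1}, 0.1, 0.1, "Oxidative phosphorylation"),
        rxn(
            "LDH",
            {"pyr_c": -1, "nadh_c": -1, "lac_c": 1},
            -cap,
            cap,
            "Glycolysis",
            "LDHA or LDHB",
        ),
        rxn("LACt", {"lac_c": -1, "lac_e": 1}, -cap, cap, SUBSYSTEM_TRANSPORT, "SLC16A1"),
        rxn(LACTATE_EXCHANGE, {"lac_e": -1}, 0, cap, SUBSYSTEM_EXCHANGE, exch=True),
        rxn("DM_co2", {"co2_c": -1}, 0, cap, SUBSYSTEM_EXCHANGE, exch=True),
        rxn("DM_atp", {"atp_c": -1}, 0, cap, SUBSYSTEM_EXCHANGE, exch=True),
        rxn("DM_nadh", {"nadh_c": -1}, 0, cap, SUBSYSTEM_EXCHANGE, exch=True),
        rxn("DM_nadph", {"nadph_c": -1}, 0, cap, SUBSYSTEM_EXCHANGE, exch=True),
        rxn("EX_aa", {"aa_e": -1}, -3, 0, SUBSYSTEM_EXCHANGE, exch=True),
        rxn("AAt", {"aa_e": -1, "aa_c": 1}, 0, cap, SUBSYSTEM_TRANSPORT),
        # lumped amino-acid catabolism: anaplerotic pyruvate + energy source
        rxn("AACAT", {"aa_c": -1, "pyr_c": 1, "nadh_c": 1, "atp_c": 1}, 0, cap, "Amino acid metabolism"),
    ]

    # peripheral single-gene amino-acid derivative conversions: metabolically
    # inert with respect to biomass, they give the discretization statistics a
    # realistic bulk of mid-expressed reactions
    mets.append(Metabolite("aad_e", "amino acid derivative pool", "e", 3))
    rxns.append(rxn("EX_aad", {"aad_e": -1}, -10, 0, SUBSYSTEM_EXCHANGE, exch=True))
    for i in range(1, 9):
        mets.append(Metabolite(f"aad{i}_c", f"amino acid derivative {i}", "c", 3))
        rxns += [
            rxn(f"AADM{i}", {"aad_e": -1, f"aad{i}_c": 1}, 0, cap,
                "Amino acid metabolism", f"AADH{i}"),
            rxn(f"DM_aad{i}", {f"aad{i}_c": -1}, 0, cap, SUBSYSTEM_EXCHANGE, exch=True),
        ]
    rxns += [
        # de novo fatty-acid synthesis: the expensive alternative to import,
        # gated by the constitutively expressed synthase
        rxn(
            "FASYN",
            {"aa_c": -2, "atp_c": -2, "facoa_c": 1},
            0,
            cap,
            SUBSYSTEM_FA_ACT,
            "FASN",
        ),
        # de novo glycan-precursor synthesis: alternative to lysosomal salvage
        rxn("GAGSYN", {"pyr_c": -2, "atp_c": -2, "gag_c": 1}, 0, cap, "Glycan biosynthesis"),
        # constitutive two-step O-glycan assembly consuming the precursor pool
        rxn("GP", {"gag_c": -1, "atp_c": -1, "gp1_c": 1}, 0, cap, "Glycan biosynthesis"),
        rxn("GP2", {"gp1_c": -1, "gp2_c": 1}, 0, cap, "Glycan biosynthesis"),
        rxn("GP3", {"gp2_c": -1, "glycoprot_c": 1}, 0, cap, "Glycan biosynthesis"),
        rxn("DM_gag", {"gag_c": -1}, 0, cap, SUBSYSTEM_EXCHANGE, exch=True),
        rxn("DM_facoa", {"facoa_c": -1}, 0, cap, SUBSYSTEM_EXCHANGE, exch=True),
        rxn("DM_pyr", {"pyr_c": -1}, 0, cap, SUBSYSTEM_EXCHANGE, exch=True),
        rxn(
            "BIOMASS",
            {
                "atp_c": -10,
                "pyr_c": -2,
                "nadph_c": -1,
                "facoa_c": -0.5,
                "glycoprot_c": -0.5,
                "biomass_c": 1,
            },
            0,
            3,  # proliferation cap keeps growth feasible on either precursor route
            "Biomass",
        ),
        rxn("DM_biomass", {"biomass_c": -1}, 0, cap, SUBSYSTEM_EXCHANGE, exch=True),
    ]

    if spec.include_gluconeogenesis_marker:
        # pyruvate -> glucose-6-phosphate analog; ATP-consuming, irreversible
        # in the gluconeogenic direction so positive flux marks the process.
        rxns.append(
            rxn(
                GLUCONEOGENESIS_MARKER,
                {"pyr_c": -2, "atp_c": -6, "nadh_c": -2, "g6p_c": 1},
                0,
                cap,
                "Gluconeogenesis",
                "FBP1 or PCK1",
            )
        )

    if spec.include_lysosomal_branch:
        mets += [
            Metabolite("hspg_e", "heparan sulfate proteoglycan", "e", 12),
            Metabolite("hs_l", "heparan sulfate", "l", 12),
            Metabolite("hsd1_l", "HS degradation product 1", "l", 12),
            Metabolite("hsd2_l", "HS degradation product 2", "l", 12),
            Metabolite("hsd3_l", "HS degradation product 3", "l", 12),
        ]
        rxns += [
            rxn("EX_hspg", {"hspg_e": -1}, -5, 0, SUBSYSTEM_EXCHANGE, exch=True),
            # endocytic uptake; no single-gene transporter, so no GPR
            rxn("HSPGt", {"hspg_e": -1, "hs_l": 1}, 0, cap, SUBSYSTEM_TRANSPORT),
            # the gated enzymatic step; downstream processing carries no GPR
            rxn("HSDEG1", {"hs_l": -1, "hsd1_l": 1}, 0, cap, SUBSYSTEM_HS_DEG, "SGSH or NAGLU or GNS"),
            rxn("HSDEG2", {"hsd1_l": -1, "hsd2_l": 1}, 0, cap, SUBSYSTEM_HS_DEG),
            rxn("HSDEG3", {"hsd2_l": -1, "hsd3_l": 1}, 0, cap, SUBSYSTEM_HS_DEG),
            # salvage export of degradation products as glycan precursor
            rxn("HSEXP", {"hsd3_l": -1, "gag_c": 2}, 0, cap, SUBSYSTEM_HS_DEG),
        ]

    if spec.include_fatty_acid_branch:
        mets += [
            Metabolite("fa_e", "nervonic acid analog", "e", 6),
            Metabolite("fa_c", "nervonic acid analog", "c", 6),
        ]
        rxns += [
            rxn("EX_fa", {"fa_e": -1}, -1, 0, SUBSYSTEM_EXCHANGE, exch=True),
            rxn(
                "FAt",
                {"fa_e": -1, "fa_c": 1},
                0,
                cap,
                SUBSYSTEM_TRANSPORT,
                "FABP1 or FABP2 or FABP4 or SLC27A1",
            ),
            rxn(
                "FAACT",
                {"fa_c": -1, "atp_c": -1, "facoa_c": 1},
                0,
                cap,
                SUBSYSTEM_FA_ACT,
                "ACSL1 or ACSL3 or ACSBG1",
            ),
        ]

    return MetabolicNetwork(
        id="toy_network",
        metabolites=mets,
        reactions=rxns,
        objective_reaction="BIOMASS",
    )


def toy_gene_families() -> dict[str, str]:
    """Gene -> family rollup map for the toy gene census."""
    fam = {
        "FABP1": "FABP",
        "FABP2": "FABP",
        "FABP4": "FABP",
        "SLC27A1": "SLC27A",
        "ACSL1": "ACSL",
        "ACSL3": "ACSL",
        "ACSBG1": "ACSBG",
        "SLC2A1": "SLC2A",
        "SLC2A2": "SLC2A",
        "SLC2A3": "SLC2A",
        "HK1": "HK",
        "HK2": "HK",
        "HK3": "HK",
        "LDHA": "LDH",
        "LDHB": "LDH",
        "SDHA": "SDH",
        "SDHB": "SDH",
        "FBP1": "GNG_GENES",
        "PCK1": "GNG_GENES",
    }
    return fam


#: deterministic baseline offsets (log2 units) for planted genes: import
#: genes are lowly expressed in the healthy state, lysosomal degradation
#: genes at the cohort baseline; the cancer class shift swaps the programs.
PLANTED_UP_BASELINE_OFFSET = -1.0
PLANTED_DOWN_BASELINE_OFFSET = 0.5
#: constitutively high ("housekeeping") genes pinned above the cohort mean
HOUSEKEEPING_BASELINE_OFFSETS = {
    "FASN": 1.0,
    "SLC2A1": 1.0,
    "HK1": 1.0,
    "GAPDH": 1.0,
    "PKM": 1.0,
    "G6PD": 1.0,
}


def simulate_expression(
    network: MetabolicNetwork,
    spec: PhenotypeSpec,
    n_decoy_genes: int = 26,
    n_zero_genes: int = 1,
) -> ExpressionMatrix:
    """Simulate a labeled FPKM-like matrix over the network's genes + decoys.

    value(g, s) = 2**(baseline_g + class_shift(g, s) + N(0, noise_sd)),
    clipped at 0, where class_shift is +effect_size for planted-up genes and
    -effect_size for planted-down genes in cancer samples.  Unplanted genes
    draw a random per-gene baseline; planted genes get fixed baselines
    (baseline_log2_mean plus the module-level offsets) so the planted shift
    is the only systematic cohort difference across seeds.  Decoy genes do
    not occur in any GPR; ``n_zero_genes`` of them are all-zero rows so the
    zero-count gene filter has work to do.  Fully reproducible from the seed.
    """
    network_genes = sorted(network.genes())
    decoys = [f"DECOY{i:03d}" for i in range(n_decoy_genes)]
    genes = network_genes + decoys
    known = set(genes)
    for g in sorted(set(spec.planted_up_genes) | set(spec.planted_down_genes)):
        if g not in known:
            raise ValueError(f"planted gene {g!r} is not a network GPR gene or decoy")

    rng = np.random.default_rng(spec.seed)
    n_h, n_c = spec.n_healthy, spec.n_cancer
    samples = [f"H{i:03d}" for i in range(n_h)] + [f"C{i:03d}" for i in range(n_c)]
    labels = {s: (HEALTHY if s.startswith("H") else CANCER) for s in samples}

    baseline = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, size=len(genes))
    shift = np.zeros((len(genes), len(samples)))
    for gi, g in enumerate(genes):
        if g in spec.planted_up_genes:
            baseline[gi] = spec.baseline_log2_mean + PLANTED_UP_BASELINE_OFFSET
            shift[gi, n_h:] = spec.effect_size
        elif g in spec.planted_down_genes:
            baseline[gi] = spec.baseline_log2_mean + PLANTED_DOWN_BASELINE_OFFSET
            shift[gi, n_h:] = -spec.effect_size
        elif g in HOUSEKEEPING_BASELINE_OFFSETS:
            baseline[gi] = spec.baseline_log2_mean + HOUSEKEEPING_BASELINE_OFFSETS[g]
    noise = rng.normal(0.0, spec.noise_sd, size=(len(genes), len(samples)))
    values = np.clip(2.0 ** (baseline[:, None] + shift + noise), 0.0, None)
    if n_zero_genes > 0:
        # dead features: last decoys carry no reads in any sample
        values[len(genes) - n_zero_genes :, :] = 0.0

    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(values=df, labels=labels, origin={s: REAL for s in samples})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_fixture_bundle(outdir, seed: int = 0) -> dict:
    """Write a self-contained fixture bundle (network, expression, labels,
    config, gene families) plus a checksum manifest; deterministic per seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    net = build_toy_network()
    spec = PhenotypeSpec(seed=seed)
    expr = simulate_expression(net, spec)

    from .core_model import write_metabolic_model

    files = {
        "network": out / "toy_network.json",
        "expression": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "config": out / "config.json",
        "gene_families": out / "gene_families.tsv",
    }
    write_metabolic_model(net, files["network"])
    write_expression_matrix(expr, files["expression"], files["labels"])
    with open(files["config"], "w") as fh:
        json.dump(
            {
                "seed": seed,
                "phenotype": {
                    "n_healthy": spec.n_healthy,
                    "n_cancer": spec.n_cancer,
                    "baseline_log2_mean": spec.baseline_log2_mean,
                    "baseline_log2_sd": spec.baseline_log2_sd,
                    "effect_size": spec.effect_size,
                    "noise_sd": spec.noise_sd,
                    "planted_up_genes": sorted(spec.planted_up_genes),
                    "planted_down_genes": sorted(spec.planted_down_genes),
                },
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    with open(files["gene_families"], "w") as fh:
        fh.write("gene\tfamily\n")
        for g, f in sorted(toy_gene_families().items()):
            fh.write(f"{g}\t{f}\n")

    manifest = {
        "seed": seed,
        "files": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in files.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
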