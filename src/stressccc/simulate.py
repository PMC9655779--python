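"""Synthetic behavioral and single-cell data with planted ground truth.

Every downstream stage of the pipeline is exercised on data generated
here, so each generator returns its truth alongside the data:

* :func:`generate_behavior` draws per-mouse zone-exploration times whose
  derived SI indices follow a three-component Gaussian mixture over the
  defeated mice (susceptible < intermediate < resilient), with control
  animals from a separate distribution and group-consistent MSI
  profiles.  The true phenotype label travels with each mouse.
* :func:`generate_counts` draws negative-binomial gene x cell counts for
  a four-group (control/R/Int/S), two-region (dorsal/ventral),
  multi-cell-type design in which, by default, only the intermediate
  group's dorsal strata carry planted fold changes -- including the
  ligand and receptor genes of planted cell-cell communication edges.
* :func:`generate_lr_reference` builds a curated-style ligand-receptor
  reference containing the planted pairs plus background pairs.
* :func:`builtin_marker_panels` returns the immediate-early-gene, CSDS
  hemoglobin, and microglial M1/M2 marker panels (MGI symbols).

Defaults encode the study design this package models: 58 defeated and
12 control mice; SI mixture means 0.40 / 0.65 / 1.30 (sd 0.05 each);
MSI profiles in which the intermediate group interacts selectively with
the unfamiliar 129/Sv strain; three mice per group in the single-cell
arm; counts parameterized by mean and dispersion
(variance = mu + mu^2 / k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BEHAVIOR_COLUMNS
from .ccc import InteractionEdge, LRReference
from .errors import ValidationError
from .preprocess import CellMatrix, MarkerPanel

__all__ = [
    "BehaviorSimSpec",
    "CountSimSpec",
    "CountTruth",
    "generate_behavior",
    "generate_counts",
    "generate_lr_reference",
    "builtin_marker_panels",
    "default_count_spec",
]

GROUPS = ("control", "R", "Int", "S")
REGIONS = ("dorsal", "ventral")
HEMISPHERES = ("left", "right")

#: 13 protein-coding genes of the mouse mitochondrial genome.
MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)

DEFAULT_CELL_TYPES = {
    "microglia": ["C1qa", "Cx3cr1", "P2ry12"],
    "oligodendrocyte": ["Plp1", "Mbp", "Mog"],
    "endothelial": ["Cldn5", "Pecam1", "Flt1"],
    "mural": ["Pdgfrb", "Rgs5", "Acta2"],
}

#: Planted communication edges: within-type Fgf1-Fgfr2 in
#: oligodendrocytes, microglial Serpine1 to the oligodendrocyte
#: receptor Lrp1b, and chemokines from three cell types converging on
#: the microglial receptor Ccr5.
DEFAULT_LR_EDGES = (
    ("oligodendrocyte", "Fgf1", "oligodendrocyte", "Fgfr2"),
    ("microglia", "Serpine1", "oligodendrocyte", "Lrp1b"),
    ("oligodendrocyte", "Ccl3", "microglia", "Ccr5"),
    ("endothelial", "Ccl4", "microglia", "Ccr5"),
    ("mural", "Ccl5", "microglia", "Ccr5"),
)


# ---------------------------------------------------------------------------
# Behavioral tables
# ---------------------------------------------------------------------------


@dataclass
class BehaviorSimSpec:
    """Stated world for the behavioral generator.

    ``component_means`` must be strictly increasing so components map
    onto S < Int < R.  ``msi_profiles`` gives each phenotype's expected
    MSI index toward the CD1 aggressor strain and the unfamiliar 129/Sv
    strain; defaults are the group medians the study design implies
    (intermediate mice interact selectively with 129/Sv).  With
    ``balanced`` the component sizes are fixed by largest-remainder
    rounding of the weights instead of drawn multinomially.
    """

    n_control: int = 12
    n_defeated: int = 58
    component_weights: tuple = (1 / 3, 1 / 3, 1 / 3)
    component_means: tuple = (0.40, 0.65, 1.30)
    component_sds: tuple = (0.05, 0.05, 0.05)
    msi_profiles: dict = field(
        default_factory=lambda: {
            "control": (1.47, 1.54),
            "R": (1.15, 0.77),
            "Int": (0.71, 1.34),
            "S": (0.53, 0.80),
        }
    )
    noise_sd: float = 0.10
    control_si_mean: float = 1.2
    control_si_sd: float = 0.15
    balanced: bool = False
    seed: int = 0

    def validate(self) -> None:
        w = np.asarray(self.component_weights, dtype=float)
        if w.size != 3 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
            raise ValidationError(
                "component_weights must be 3 non-negative values summing to 1"
            )
        sds = np.asarray(self.component_sds, dtype=float)
        if sds.size != 3 or (sds < 0).any():
            raise ValidationError("component_sds must be 3 non-negative values")
        means = np.asarray(self.component_means, dtype=float)
        if means.size != 3 or not (np.diff(means) > 0).all():
            raise ValidationError(
                "component_means must be strictly increasing (S < Int < R)"
            )
        if self.n_control < 0 or self.n_defeated < 1:
            raise ValidationError("need n_defeated >= 1 and n_control >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        for ph in ("control", "R", "Int", "S"):
            if ph not in self.msi_profiles:
                raise ValidationError(f"msi_profiles missing phenotype {ph!r}")


def _zone_times_from_si(rng, si: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # 2.5 min test phase: empty-enclosure exploration 30-60 s
    t_empty = rng.uniform(30.0, 60.0, size=si.size)
    return si * t_empty, t_empty


def generate_behavior(spec: BehaviorSimSpec) -> pd.DataFrame:
    """Draw a behavioral table whose SI indices follow the spec's mixture.

    Returns one row per mouse with raw zone times (SI and MSI arenas),
    derived indices and the generating ``true_label``.  Deterministic
    for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels_by_comp = np.array(["S", "Int", "R"])
    w = np.asarray(spec.component_weights)
    if spec.balanced:
        # deterministic component sizes (largest-remainder rounding)
        sizes = np.floor(w * spec.n_defeated).astype(int)
        frac_order = np.argsort(-(w * spec.n_defeated - sizes))
        for i in range(spec.n_defeated - sizes.sum()):
            sizes[frac_order[i % 3]] += 1
        comp = rng.permutation(np.repeat(np.arange(3), sizes))
    else:
        comp = rng.choice(3, size=spec.n_defeated, p=w)
    means = np.asarray(spec.component_means, float)
    sds = np.asarray(spec.component_sds, float)
    si_def = rng.normal(means[comp], sds[comp])
    si_ctl = rng.normal(spec.control_si_mean, spec.control_si_sd, spec.n_control)
    si = np.clip(np.concatenate([si_ctl, si_def]), 1e-6, None)
    labels = np.concatenate(
        [np.repeat("control", spec.n_control), labels_by_comp[comp]]
    )
    condition = np.concatenate(
        [np.repeat("control", spec.n_control), np.repeat("defeated", spec.n_defeated)]
    )
    n = si.size
    t_target, t_empty = _zone_times_from_si(rng, si)
    # 6 min MSI habituation: 25-45 s at each empty enclosure
    t_hab_left = rng.uniform(25.0, 45.0, n)
    t_hab_right = rng.uniform(25.0, 45.0, n)
    hab_mean = (t_hab_left + t_hab_right) / 2.0
    profiles = np.array([spec.msi_profiles[l] for l in labels])
    msi = np.clip(profiles + rng.normal(0.0, spec.noise_sd, (n, 2)), 0.0, None)
    table = pd.DataFrame(
        {
            "id": [f"m{i + 1:03d}" for i in range(n)],
            "condition": condition,
            "t_target": t_target,
            "t_empty": t_empty,
            "t_cd1": msi[:, 0] * hab_mean,
            "t_129sv": msi[:, 1] * hab_mean,
            "t_hab_left": t_hab_left,
            "t_hab_right": t_hab_right,
            "true_label": labels,
        }
    )[BEHAVIOR_COLUMNS + ["true_label"]]
    table["si_index"] = si
    table["msi_cd1"] = msi[:, 0]
    table["msi_129"] = msi[:, 1]
    return table


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountSimSpec:
    """Stated world for the count generator.

    ``planted_degs`` maps a (group, region, cell_type) stratum to
    {gene: fold change}; fold changes multiply the gene's NB mean in
    that stratum only, so the true natural-log fold change is ln(fc).
    ``planted_lr_edges`` lists (source_type, ligand, target_type,
    receptor) tuples whose ligand/receptor genes must be planted as
    DEGs of the source/target stratum respectively.
    """

    cell_types: dict = field(default_factory=lambda: dict(DEFAULT_CELL_TYPES))
    n_genes: int = 1000
    n_cells_per_stratum: int = 200
    baseline_mean: float = 0.8
    baseline_sigma: float = 1.0
    nb_dispersion: float = 2.0
    marker_multiplier: float = 8.0
    mito_baseline: float = 5.0
    planted_degs: dict = field(default_factory=dict)
    planted_lr_edges: tuple = ()
    planted_baseline: float = 1.0
    mouse_effect_sd: float = 0.05
    n_mice_per_group: int = 3
    mito_gene_prefix: str = "mt-"
    seed: int = 0

    def gene_universe(self) -> list[str]:
        """Deterministic gene universe: markers, LR genes, mito genes,
        then generic filler symbols up to ``n_genes``."""
        named: list[str] = []
        for markers in self.cell_types.values():
            named.extend(markers)
        for _, lig, _, rec in self.planted_lr_edges:
            for g in (lig, rec):
                if g not in named:
                    named.append(g)
        named.extend(MITO_GENES)
        if len(named) != len(set(named)):
            dupes = sorted({g for g in named if named.count(g) > 1})
            raise ValidationError(f"duplicate named genes: {dupes}")
        if len(named) > self.n_genes:
            raise ValidationError(
                f"n_genes={self.n_genes} too small for {len(named)} named genes"
            )
        named_set = set(named)
        fill: list[str] = []
        i = 1
        while len(named) + len(fill) < self.n_genes:
            g = f"G{i:04d}"
            if g not in named_set:
                fill.append(g)
            i += 1
        return named + fill

    def validate(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if self.n_cells_per_stratum < 1:
            raise ValidationError("n_cells_per_stratum must be >= 1")
        universe = set(self.gene_universe())
        for stratum, genes in self.planted_degs.items():
            group, region, ctype = stratum
            if group not in GROUPS or region not in REGIONS:
                raise ValidationError(f"unknown stratum {stratum!r}")
            if ctype not in self.cell_types:
                raise ValidationError(f"unknown cell type in stratum {stratum!r}")
            for g, fc in genes.items():
                if g not in universe:
                    raise ValidationError(f"planted gene {g!r} not in universe")
                if fc <= 0:
                    raise ValidationError(f"fold change for {g!r} must be > 0")
        for src, lig, tgt, rec in self.planted_lr_edges:
            found_l = any(
                lig in self.planted_degs.get((g, r, src), {})
                for g in GROUPS for r in REGIONS
            )
            found_r = any(
                rec in self.planted_degs.get((g, r, tgt), {})
                for g in GROUPS for r in REGIONS
            )
            if not (found_l and found_r):
                raise ValidationError(
                    f"LR edge ({src},{lig})->({tgt},{rec}) not backed by "
                    "planted DEGs in its source/target strata"
                )


@dataclass
class CountTruth:
    """Ground truth accompanying a generated count matrix."""

    degs: pd.DataFrame  # group, region, cell_type, gene, fold_change, true_logfc
    lr_edges: list[InteractionEdge]
    baselines: pd.Series  # per-gene baseline NB mean


def default_count_spec(
    seed: int = 0,
    n_genes: int = 1000,
    n_cells_per_stratum: int = 200,
    fold_change: float = 3.0,
    n_planted_per_type: int = 15,
) -> CountSimSpec:
    """The default stated world: planted effects only in (Int, dorsal).

    Each cell type receives ``n_planted_per_type`` generic planted DEGs
    at ``fold_change`` plus its ligand/receptor genes from
    :data:`DEFAULT_LR_EDGES`, all restricted to the intermediate
    group's dorsal stratum.
    """
    planted: dict[tuple, dict[str, float]] = {
        ("Int", "dorsal", ct): {} for ct in DEFAULT_CELL_TYPES
    }
    for src, lig, tgt, rec in DEFAULT_LR_EDGES:
        planted[("Int", "dorsal", src)][lig] = fold_change
        planted[("Int", "dorsal", tgt)][rec] = fold_change
    for i, ct in enumerate(DEFAULT_CELL_TYPES):
        for j in range(n_planted_per_type):
            planted[("Int", "dorsal", ct)][
                f"G{i * n_planted_per_type + j + 1:04d}"
            ] = fold_change
    return CountSimSpec(
        n_genes=n_genes,
        n_cells_per_stratum=n_cells_per_stratum,
        planted_degs=planted,
        planted_lr_edges=DEFAULT_LR_EDGES,
        seed=seed,
    )


def generate_counts(spec: CountSimSpec) -> tuple[CellMatrix, CountTruth]:
    """Draw NB counts for the full (group x region x cell type) design.

    Counts are negative binomial with variance mu + mu^2/k.  Gene
    baselines are lognormal (median ``baseline_mean``); marker genes
    are elevated ``marker_multiplier``-fold in their own cell type;
    planted genes get baseline ``planted_baseline`` and their fold
    change multiplies the mean only in the planted stratum.  Each
    group's cells are split over ``n_mice_per_group`` mice carrying a
    lognormal random effect (sd ``mouse_effect_sd``, set 0 for a clean
    null) and over both hemispheres.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_universe()
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    baseline = spec.baseline_mean * rng.lognormal(
        mean=0.0, sigma=spec.baseline_sigma, size=n_genes
    )
    for g in MITO_GENES:
        baseline[gene_idx[g]] = spec.mito_baseline
    planted_genes = {g for genes_ in spec.planted_degs.values() for g in genes_}
    for g in planted_genes:
        baseline[gene_idx[g]] = max(baseline[gene_idx[g]], spec.planted_baseline)
    for markers in spec.cell_types.values():
        for g in markers:
            baseline[gene_idx[g]] = max(baseline[gene_idx[g]], spec.planted_baseline)

    mouse_effect = {}
    for group in GROUPS:
        for m in range(spec.n_mice_per_group):
            mouse_effect[f"{group}_m{m + 1}"] = (
                rng.lognormal(0.0, spec.mouse_effect_sd)
                if spec.mouse_effect_sd > 0
                else 1.0
            )

    blocks, metas = [], []
    k = spec.nb_dispersion
    for group in GROUPS:
        for region in REGIONS:
            for ctype, markers in spec.cell_types.items():
                mu_g = baseline.copy()
                for g in markers:
                    mu_g[gene_idx[g]] *= spec.marker_multiplier
                for g, fc in spec.planted_degs.get((group, region, ctype), {}).items():
                    mu_g[gene_idx[g]] *= fc
                n_cells = spec.n_cells_per_stratum
                mice = [
                    f"{group}_m{c % spec.n_mice_per_group + 1}"
                    for c in range(n_cells)
                ]
                eff = np.array([mouse_effect[m] for m in mice])
                mu = mu_g[:, None] * eff[None, :]
                counts = rng.negative_binomial(n=k, p=k / (k + mu))
                blocks.append(counts)
                metas.append(
                    pd.DataFrame(
                        {
                            "mouse": mice,
                            "group": group,
                            "region": region,
                            "hemisphere": [
                                HEMISPHERES[c % 2] for c in range(n_cells)
                            ],
                            "cell_type": ctype,
                        },
                        index=[
                            f"{group}_{region}_{ctype}_{c + 1:04d}"
                            for c in range(n_cells)
                        ],
                    )
                )
    from scipy import sparse

    matrix = CellMatrix(
        counts=sparse.csr_matrix(np.hstack(blocks)),
        gene_ids=genes,
        cell_meta=pd.concat(metas),
    )
    deg_rows = [
        {
            "group": group,
            "region": region,
            "cell_type": ctype,
            "gene": g,
            "fold_change": fc,
            "true_logfc": float(np.log(fc)),
        }
        for (group, region, ctype), gmap in sorted(spec.planted_degs.items())
        for g, fc in sorted(gmap.items())
    ]
    truth = CountTruth(
        degs=pd.DataFrame(
            deg_rows,
            columns=["group", "region", "cell_type", "gene", "fold_change",
                     "true_logfc"],
        ),
        lr_edges=[InteractionEdge(*e) for e in spec.planted_lr_edges],
        baselines=pd.Series(baseline, index=genes),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Ligand-receptor reference and marker panels
# ---------------------------------------------------------------------------


def generate_lr_reference(
    n_background_pairs: int,
    planted,
    seed: int = 0,
    gene_pool=None,
) -> LRReference:
    """Planted (ligand, receptor) pairs plus unique background pairs.

    Background pairs are drawn over ``gene_pool`` minus all planted
    genes when a pool is supplied (so background interactions are real
    genes of the expression universe), otherwise over synthetic
    ``bgL####``/``bgR####`` symbols.  Roles are positional: a gene may
    be a ligand in one row and a receptor in another.
    """
    planted = [tuple(map(str, p)) for p in planted]
    if len(planted) != len(set(planted)):
        raise ValidationError("duplicate planted ligand-receptor pair")
    for lig, rec in planted:
        if lig == rec:
            raise ValidationError(
                f"planted pair ({lig}, {rec}) must have distinct symbols"
            )
    if n_background_pairs < 0:
        raise ValidationError("n_background_pairs must be >= 0")
    rng = np.random.default_rng(seed)
    pairs = set(planted)
    planted_genes = {g for p in planted for g in p}
    if gene_pool is not None:
        pool = sorted(set(map(str, gene_pool)) - planted_genes)
        if n_background_pairs and len(pool) < 2:
            raise ValidationError("gene_pool too small for background pairs")
        guard = 0
        while len(pairs) < len(planted) + n_background_pairs:
            lig, rec = rng.choice(pool, size=2, replace=False)
            if (lig, rec) not in pairs:
                pairs.add((lig, rec))
            guard += 1
            if guard > 100 * (n_background_pairs + 1):
                raise ValidationError("could not draw enough unique pairs")
    else:
        for i in range(n_background_pairs):
            pairs.add((f"bgL{i + 1:04d}", f"bgR{i + 1:04d}"))
    return LRReference(pairs=frozenset(pairs), source_tag="synthetic")


def builtin_marker_panels() -> dict[str, MarkerPanel]:
    """Built-in marker panels under standard MGI symbols.

    IEG: immediate early genes; CSDS: hemoglobin chronic-defeat
    markers; M1 / M2: pro-inflammatory versus alternative
    neuroprotective microglial activation markers.  Panels are pairwise
    disjoint.
    """
    panels = {
        "IEG": {"Arc", "Egr1", "Fos", "Jun"},
        "CSDS": {"Hba-a1", "Hba-a2", "Hbb-bs"},
        "M1": {
            "Cxcl10", "Fcgr2b", "Fcgr3", "H2-Aa", "H2-D1", "H2-Dmb1",
            "H2-K1", "H2-Oa", "H2-Q4", "H2-Q6", "H2-T23", "Tnfaip2",
            "Tnfaip8l2", "Il1b",
        },
        "M2": {"Il10ra", "Socs3", "Tgfb1"},
    }
    return {name: MarkerPanel(name=name, genes=frozenset(g))
            for name, g in panels.items()}
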