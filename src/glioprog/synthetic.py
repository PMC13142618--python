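"""Seeded synthetic cohorts emulating glial multicellular programs.

The generator produces sparse gene-by-cell count matrices, cell/donor
metadata, and 2-D spatial samples with the statistical structure the
downstream pipeline assumes: donors nested in condition/region/Braak stage,
glial subpopulations with planted marker programs, donor-group-dependent
compositions in which UPR-program and Reactive-program subpopulations covary
within a donor but are mutually exclusive across donors, negative-binomial
counts with ambient contamination, doublets, and gray/white-matter spatial
domains.

Nothing here attempts to mimic real striatal expression profiles; the point
is a controllable ground truth for every statistical operation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

# ---------------------------------------------------------------------------
# Cohort structure: subpopulations, programs, cell classes
# ---------------------------------------------------------------------------

#: subpopulation -> multicellular program it marks
PROGRAM_OF_SUBPOP: dict[str, str] = {
    "A0": "homeostatic",
    "AR1": "UPR",
    "AR2": "reactive",
    "SVZC": "neutral",
    "MH": "homeostatic",
    "MH-HSP": "UPR",
    "M1": "reactive",
    "MOL": "homeostatic",
    "PDAO": "UPR",
    "OPC": "neutral",
}

#: subpopulation -> major cell class
CLASS_OF_SUBPOP: dict[str, str] = {
    "A0": "Astrocyte",
    "AR1": "Astrocyte",
    "AR2": "Astrocyte",
    "SVZC": "Astrocyte",
    "MH": "Microglia",
    "MH-HSP": "Microglia",
    "M1": "Microglia",
    "MOL": "Oligodendrocyte",
    "PDAO": "Oligodendrocyte",
    "OPC": "OPC",
}

DEFAULT_SUBPOPS = list(PROGRAM_OF_SUBPOP)

#: donor group -> mean subpopulation proportions (rows sum to 1).
#: UPR-high donors are dominated by AR1 astrocytes, MH-HSP microglia and
#: PDAO oligodendroglia; Reactive donors by AR2 astrocytes and M1 microglia;
#: Homeostatic donors keep both program blocks rare. The planted astrocyte /
#: microglia fractions sit far from the 10% stratification boundary on both
#: sides, mirroring the near-total within-donor program dominance the model
#: assumes.
DEFAULT_COMPOSITION_MEANS = pd.DataFrame(
    {
        "A0":     [0.20, 0.22, 0.40],
        "AR1":    [0.25, 0.01, 0.01],
        "AR2":    [0.01, 0.20, 0.01],
        "SVZC":   [0.02, 0.02, 0.02],
        "MH":     [0.11, 0.12, 0.24],
        "MH-HSP": [0.15, 0.01, 0.01],
        "M1":     [0.01, 0.18, 0.01],
        "MOL":    [0.13, 0.16, 0.20],
        "PDAO":   [0.08, 0.03, 0.04],
        "OPC":    [0.04, 0.05, 0.06],
    },
    index=["UPR", "Reactive", "Homeostatic"],
)

DEFAULT_BRAAK = {
    "UPR": {4: 0.3, 5: 0.4, 6: 0.3},
    "Reactive": {2: 0.2, 3: 0.3, 4: 0.3, 5: 0.2},
    "Homeostatic": {0: 0.6, 1: 0.2, 2: 0.2},
}

CONDITION_OF_GROUP = {"UPR": "PD", "Reactive": "PD", "Homeostatic": "Control"}

REGIONS = ("Pu", "CN")


@dataclass
class CohortConfig:
    """Parameters of the synthetic snRNA-seq cohort.

    ``composition_means`` rows index donor groups and must each sum to 1;
    ``marker_lfc`` is the log2 enrichment of a subpopulation's markers within
    that subpopulation (class markers behave identically at the class level).
    """

    n_donors_per_group: dict[str, int] = field(
        default_factory=lambda: {"UPR": 10, "Reactive": 10, "Homeostatic": 10}
    )
    subpop_names: list[str] = field(default_factory=lambda: list(DEFAULT_SUBPOPS))
    composition_means: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_COMPOSITION_MEANS.copy()
    )
    composition_concentration: float = 300.0
    n_cells_per_donor: int = 1000
    n_genes: int = 600
    n_markers_per_subpop: int = 20
    n_markers_per_class: int = 20
    marker_lfc: float = 2.0
    # canonical cell-class markers are near-exclusive in real tissue, unlike
    # the graded subtype-state markers, hence the much larger enrichment
    class_marker_lfc: float = 5.0
    nb_dispersion: float = 0.3
    ambient_fraction: float = 0.05
    doublet_rate: float = 0.0
    mito_gene_fraction: float = 0.05
    mito_count_share: float = 0.05
    library_size: float = 2500.0
    braak_assignment: dict[str, dict[int, float]] = field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_BRAAK.items()}
    )
    upr_male_only: bool = True
    regions: tuple[str, ...] = REGIONS
    seed: int = 0

    def validate(self) -> None:
        means = self.composition_means
        rowsums = means.sum(axis=1).to_numpy()
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("composition_means rows must sum to 1 within 1e-9")
        if (means.to_numpy() < 0).any():
            raise ValueError("composition_means must be non-negative")
        if not 0 <= self.doublet_rate < 0.5:
            raise ValueError("doublet_rate must be in [0, 0.5)")
        if not 0 <= self.ambient_fraction < 1:
            raise ValueError("ambient_fraction must be in [0, 1)")
        if set(means.columns) != set(self.subpop_names):
            raise ValueError("composition_means columns must match subpop_names")
        missing = set(self.n_donors_per_group) - set(means.index)
        if missing:
            raise ValueError(f"no composition row for donor groups: {sorted(missing)}")
        # a group mean implying < 1 expected cell for a subpopulation signals
        # an unusable cohort scale
        positive = means.to_numpy()[means.to_numpy() > 0]
        if positive.size and (positive * self.n_cells_per_donor).min() < 1:
            raise ValueError(
                "expected subpopulation cell counts below 1; "
                "increase n_cells_per_donor or composition means"
            )


@dataclass
class CountMatrix:
    """Sparse cells x genes integer counts with id lists and gene metadata.

    ``gene_flags`` is the boolean mitochondrial indicator; ``gene_meta``
    additionally records which subpopulation or cell class each planted
    marker gene belongs to (empty string for background genes).
    """

    counts: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    gene_flags: np.ndarray
    gene_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n, g = self.counts.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise ValueError("counts shape inconsistent with id lists")
        if len(self.gene_flags) != g:
            raise ValueError("gene_flags length inconsistent with gene_ids")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def marker_sets(self, level: str = "subpopulation") -> dict[str, list[str]]:
        """Planted marker gene sets, keyed by subpopulation or cell class."""
        if self.gene_meta is None:
            raise ValueError("this matrix carries no marker annotation")
        col = {"subpopulation": "marker_of_subpop", "cell_class": "marker_of_class"}[level]
        out: dict[str, list[str]] = {}
        for key, grp in self.gene_meta.groupby(col):
            if key:
                out[str(key)] = list(grp.index)
        return out


# ---------------------------------------------------------------------------
# Expression model
# ---------------------------------------------------------------------------


def _base_profiles(config: CohortConfig, rng: np.random.Generator):
    """Per-subpopulation mean expression profiles on the simplex.

    Background gene weights are log-normal; markers multiply their weight by
    2**marker_lfc in the subpopulations (or classes) that carry them, after
    which the non-mitochondrial block is renormalised so every profile keeps
    ``mito_count_share`` of its mass on mitochondrial genes.
    """
    g = config.n_genes
    n_mito = int(round(config.mito_gene_fraction * g))
    gene_ids = [f"MT-G{i:04d}" for i in range(n_mito)]
    gene_ids += [f"GENE{i:04d}" for i in range(g - n_mito)]
    is_mito = np.zeros(g, dtype=bool)
    is_mito[:n_mito] = True

    base = rng.lognormal(mean=0.0, sigma=1.0, size=g)

    # assign marker blocks among non-mito genes
    marker_of_subpop = np.array([""] * g, dtype=object)
    marker_of_class = np.array([""] * g, dtype=object)
    free = list(np.flatnonzero(~is_mito))
    rng.shuffle(free)
    cursor = 0
    for sp_name in config.subpop_names:
        idx = free[cursor : cursor + config.n_markers_per_subpop]
        cursor += config.n_markers_per_subpop
        marker_of_subpop[idx] = sp_name
    classes = sorted(set(CLASS_OF_SUBPOP[s] for s in config.subpop_names))
    for cls in classes:
        idx = free[cursor : cursor + config.n_markers_per_class]
        cursor += config.n_markers_per_class
        marker_of_class[idx] = cls
    if cursor > len(free):
        raise ValueError("not enough non-mitochondrial genes for the marker blocks")

    fold = 2.0 ** config.marker_lfc
    class_fold = 2.0 ** config.class_marker_lfc
    profiles = {}
    for sp_name in config.subpop_names:
        w = base.copy()
        w[marker_of_subpop == sp_name] *= fold
        w[marker_of_class == CLASS_OF_SUBPOP[sp_name]] *= class_fold
        w_mito = w[is_mito]
        w_rest = w[~is_mito]
        prof = np.empty(g)
        prof[is_mito] = config.mito_count_share * w_mito / w_mito.sum()
        prof[~is_mito] = (1 - config.mito_count_share) * w_rest / w_rest.sum()
        profiles[sp_name] = prof

    gene_meta = pd.DataFrame(
        {
            "is_mito": is_mito,
            "marker_of_subpop": marker_of_subpop,
            "marker_of_class": marker_of_class,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return gene_ids, is_mito, profiles, gene_meta


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_cohort(config: CohortConfig):
    """Generate a full synthetic cohort.

    Returns ``(CountMatrix, annotations, donor_truth)`` where annotations has
    one row per cell (cell_id, donor_id, region, condition, braak_stage, sex,
    cell_class, subpopulation, doublet truth columns) and donor_truth one row
    per donor with its planted group and drawn subpopulation proportions.
    Deterministic under a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids, is_mito, profiles, gene_meta = _base_profiles(config, rng)
    subpops = config.subpop_names
    prof_matrix = np.vstack([profiles[s] for s in subpops])

    blocks = []
    ann_rows = []
    truth_rows = []
    donor_no = 0
    for group in config.n_donors_per_group:
        means = config.composition_means.loc[group, subpops].to_numpy(dtype=float)
        alpha = means * config.composition_concentration
        braak_map = config.braak_assignment[group]
        stages = np.array(list(braak_map), dtype=int)
        stage_p = np.array(list(braak_map.values()), dtype=float)
        stage_p = stage_p / stage_p.sum()
        for _ in range(config.n_donors_per_group[group]):
            donor_id = f"D{donor_no:03d}"
            donor_no += 1
            props = rng.dirichlet(np.where(alpha > 0, alpha, 1e-6))
            props[means == 0] = 0.0
            props = props / props.sum()
            n_cells = int(config.n_cells_per_donor)
            subpop_idx = rng.choice(len(subpops), size=n_cells, p=props)
            region_idx = rng.integers(0, len(config.regions), size=n_cells)
            braak = int(rng.choice(stages, p=stage_p))
            sex = "M" if (config.upr_male_only and group == "UPR") else ("M", "F")[rng.integers(0, 2)]
            condition = CONDITION_OF_GROUP.get(group, "PD")

            lib = rng.lognormal(np.log(config.library_size), 0.25, size=n_cells)
            cell_means = lib[:, None] * prof_matrix[subpop_idx]
            if config.ambient_fraction > 0:
                pooled = props @ prof_matrix
                cell_means = (
                    (1 - config.ambient_fraction) * cell_means
                    + config.ambient_fraction * lib[:, None] * pooled[None, :]
                )
            counts = _nb_draw(rng, cell_means, config.nb_dispersion)
            blocks.append(sp.csr_matrix(counts))

            for i in range(n_cells):
                s = subpops[subpop_idx[i]]
                ann_rows.append(
                    (
                        f"{donor_id}_C{i:05d}",
                        donor_id,
                        config.regions[region_idx[i]],
                        condition,
                        braak,
                        sex,
                        CLASS_OF_SUBPOP[s],
                        s,
                        False,
                        "",
                    )
                )
            truth_rows.append(
                (donor_id, group, condition, braak, sex, *props)
            )

    counts = sp.vstack(blocks, format="csr")
    annotations = pd.DataFrame(
        ann_rows,
        columns=[
            "cell_id", "donor_id", "region", "condition", "braak_stage",
            "sex", "cell_class", "subpopulation", "is_doublet_truth",
            "doublet_partner_class",
        ],
    )
    donor_truth = pd.DataFrame(
        truth_rows,
        columns=["donor_id", "group", "condition", "braak_stage", "sex", *subpops],
    )
    cm = CountMatrix(
        counts=counts,
        cell_ids=list(annotations["cell_id"]),
        gene_ids=gene_ids,
        gene_flags=is_mito,
        gene_meta=gene_meta,
    )
    if config.doublet_rate > 0:
        cm, annotations = inject_doublets(
            cm, annotations, config.doublet_rate, seed=rng.integers(0, 2**31)
        )
    return cm, annotations, donor_truth


def inject_doublets(
    matrix: CountMatrix,
    annotations: pd.DataFrame,
    rate: float,
    seed: int,
    heterotypic_only: bool = False,
):
    """Append synthetic doublets formed by summing two sampled parents.

    ``round(rate * n)`` doublet rows are appended; each doublet's counts are
    the exact sum of its parents', so its total UMI equals the parents' sum.
    A doublet is heterotypic iff its parents differ in cell_class; with
    ``heterotypic_only`` parent pairs are drawn from distinct classes.
    """
    if not 0 <= rate < 0.5:
        raise ValueError("doublet rate must be in [0, 0.5)")
    n = matrix.n_cells
    n_dbl = int(round(rate * n))
    if n_dbl == 0:
        return matrix, annotations.copy()
    rng = np.random.default_rng(seed)
    classes = annotations["cell_class"].to_numpy()
    pairs = []
    while len(pairs) < n_dbl:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        if heterotypic_only and classes[i] == classes[j]:
            continue
        pairs.append((int(i), int(j)))
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    dbl_counts = matrix.counts[ii] + matrix.counts[jj]
    new_counts = sp.vstack([matrix.counts, dbl_counts], format="csr")

    parent = annotations.iloc[ii].reset_index(drop=True)
    dbl_ann = parent.copy()
    dbl_ann["cell_id"] = [f"DBL{k:05d}" for k in range(n_dbl)]
    dbl_ann["is_doublet_truth"] = True
    dbl_ann["doublet_partner_class"] = classes[jj]
    out_ann = pd.concat([annotations, dbl_ann], ignore_index=True)
    out = CountMatrix(
        counts=new_counts,
        cell_ids=list(out_ann["cell_id"]),
        gene_ids=list(matrix.gene_ids),
        gene_flags=matrix.gene_flags,
        gene_meta=matrix.gene_meta,
    )
    return out, out_ann


# ---------------------------------------------------------------------------
# Spatial samples
# ---------------------------------------------------------------------------


@dataclass
class SpatialConfig:
    """Parameters of a synthetic imaging-ST sample.

    Domains are laid out geometrically: an optional ventricle strip on the
    left edge, vertical white-matter bands through the tissue, vascular
    cells scattered through the gray matter, the rest gray matter. Truth
    spatial genes are expressed at ``spatial_rate`` inside circular patches
    and at ``base_rate`` elsewhere; the remaining panel genes are
    position-independent.
    """

    n_cells: int = 5000
    width_um: float = 3000.0
    height_um: float = 3000.0
    domain_targets: dict[str, float] = field(
        default_factory=lambda: {"GM": 0.721, "WM": 0.190, "Vascular": 0.051, "Ventricle": 0.028}
    )
    n_wm_bands: int = 3
    n_panel_genes: int = 40
    n_spatial_genes: int = 5
    base_rate: float = 0.2
    spatial_rate: float = 6.0
    n_patches: int = 4
    patch_radius_um: float = 350.0
    sample_id: str = "S0"


@dataclass
class SpatialSample:
    """One imaging-ST sample: coordinates, domain labels, panel counts."""

    sample_id: str
    cell_ids: list[str]
    x_um: np.ndarray
    y_um: np.ndarray
    domain: np.ndarray
    panel_genes: list[str]
    panel_counts: np.ndarray
    truth_spatial_genes: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "cell_id": self.cell_ids,
                "x_um": self.x_um,
                "y_um": self.y_um,
                "domain": self.domain,
            }
        )
        return pd.concat(
            [df, pd.DataFrame(self.panel_counts, columns=self.panel_genes)], axis=1
        )


def generate_spatial_sample(config: SpatialConfig, seed: int) -> SpatialSample:
    """Generate one seeded spatial sample on a uniform random point field."""
    rng = np.random.default_rng(seed)
    targets = dict(config.domain_targets)
    total = sum(targets.values())
    targets = {k: v / total for k, v in targets.items()}
    W, H = config.width_um, config.height_um
    x = rng.uniform(0, W, size=config.n_cells)
    y = rng.uniform(0, H, size=config.n_cells)

    f_vent = targets.get("Ventricle", 0.0)
    f_wm = targets.get("WM", 0.0)
    f_vasc = targets.get("Vascular", 0.0)

    domain = np.array(["GM"] * config.n_cells, dtype=object)
    vent_w = f_vent * W
    in_vent = x < vent_w
    domain[in_vent] = "Ventricle"

    # vertical WM bands across the non-ventricular tissue
    usable_w = W - vent_w
    band_total = f_wm / (1 - f_vent) * usable_w if f_vent < 1 else 0.0
    band_w = band_total / max(config.n_wm_bands, 1)
    gap = (usable_w - band_total) / (config.n_wm_bands + 1)
    for b in range(config.n_wm_bands):
        x0 = vent_w + gap * (b + 1) + band_w * b
        sel = (~in_vent) & (x >= x0) & (x < x0 + band_w)
        domain[sel] = "WM"

    # vascular structures pervade the gray matter: random subset of GM points
    gm_idx = np.flatnonzero(domain == "GM")
    p_vasc = f_vasc / max(f_vasc + targets.get("GM", 0.0), 1e-12)
    vasc_sel = gm_idx[rng.random(gm_idx.size) < p_vasc]
    domain[vasc_sel] = "Vascular"

    n_sp = config.n_spatial_genes
    genes = [f"SPG{i:03d}" for i in range(n_sp)]
    genes += [f"PAN{i:03d}" for i in range(config.n_panel_genes - n_sp)]
    counts = np.empty((config.n_cells, config.n_panel_genes), dtype=np.int64)

    gm_mask = domain == "GM"
    gm_x, gm_y = x[gm_mask], y[gm_mask]
    for gi in range(config.n_panel_genes):
        if gi < n_sp:
            rate = np.full(config.n_cells, config.base_rate)
            for _ in range(config.n_patches):
                k = rng.integers(0, gm_x.size)
                cx, cy = gm_x[k], gm_y[k]
                d2 = (x - cx) ** 2 + (y - cy) ** 2
                rate[d2 < config.patch_radius_um**2] = config.spatial_rate
            counts[:, gi] = rng.poisson(rate)
        else:
            lam = rng.lognormal(-0.7, 0.6)
            counts[:, gi] = rng.poisson(lam, size=config.n_cells)

    return SpatialSample(
        sample_id=config.sample_id,
        cell_ids=[f"{config.sample_id}_X{i:05d}" for i in range(config.n_cells)],
        x_um=x,
        y_um=y,
        domain=domain,
        panel_genes=genes,
        panel_counts=counts,
        truth_spatial_genes=genes[:n_sp],
    )
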