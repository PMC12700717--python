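"""Seeded synthetic study generator.

The cohort data behind this pipeline (transrectal ultrasound images, CEUS
time–intensity curves, RNA-seq counts and clinical covariates of healthy
controls and T2c/T3b prostate-cancer patients) are not public, so every
downstream stage is driven by a synthetic study with the statistical
structure those stages assume:

* images — multiplicative gamma speckle over a smooth background, with the
  speckle correlation length and local variance inside an elliptical ROI
  shifted by stage so texture features separate T2c from T3b at a
  configurable effect size;
* TICs — mono-exponential refill curves I(t) = A(1 - exp(-beta t)) with
  stage-dependent (A, beta) and Gaussian noise, true parameters returned;
* expression — negative-binomial counts with planted stage-specific DE
  features, the six-biomarker panel (FZD4/RPS7/RPL29/miR-9-3p up in T3b,
  miR-374c/miR-6510 down), and monotone-trend features feeding the
  regulatory-network stage;
* clinical covariates — truncated-normal draws from the published cohort
  group moments (healthy-control moments are this generator's own choice);
* interactions — a planted miRNA->gene bipartite graph whose four hubs
  jointly cover nine target genes, plus low-degree decoy edges.

Every generator is a pure function of (config, seed): reruns are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import truncnorm

from .perfusion import TICurve

__all__ = [
    "StudyConfig", "SyntheticImage", "SyntheticStudy",
    "gen_images", "gen_tics", "gen_expression", "gen_clinical",
    "gen_interactions", "generate_study",
    "BIOMARKER_PANEL", "BIOMARKER_DIRECTIONS", "HUB_MIRNAS", "TARGET_GENES",
]

GROUPS = ("healthy", "T2c", "T3b")

#: The six-biomarker panel with its T3b-vs-T2c directions.
BIOMARKER_DIRECTIONS = {
    "FZD4": "up", "RPS7": "up", "RPL29": "up", "miR-9-3p": "up",
    "miR-374c": "down", "miR-6510": "down",
}
BIOMARKER_PANEL = tuple(BIOMARKER_DIRECTIONS)
BIOMARKER_MRNAS = ("FZD4", "RPS7", "RPL29")
BIOMARKER_MIRNAS = ("miR-9-3p", "miR-374c", "miR-6510")

#: Planted monotone-trend features (network fodder).
MONOTONE_DEC_GENES = (
    "CXCL12", "PECAM1", "LEF1", "GADD45A", "THBS1", "COL1A1",
    "VEGFA", "SMAD7", "ITGA3", "NECTIN2", "IGF1", "PTGS2",
)
MONOTONE_INC_MIRNAS = ("miR-148", "miR-141", "miR-342", "miR-210",
                       "miR-500a", "miR-501b")
#: Planted network hubs (first four increasing miRNAs) and their nine targets.
HUB_MIRNAS = MONOTONE_INC_MIRNAS[:4]
TARGET_GENES = MONOTONE_DEC_GENES[:9]
_HUB_DEGREES = (3, 2, 2, 2)  # jointly cover the nine targets

#: Clinical group moments (mean, sd) per covariate.  Tumor-stage rows follow
#: the published cohort summary; healthy-control moments are generator
#: conventions (controls are not summarized there).
CLINICAL_MOMENTS = {
    "T2c": {"age": (70.11, 7.90), "tPSA": (42.11, 33.66),
            "fPSA_ratio": (0.12, 0.07), "trus_volume": (41.57, 20.03),
            "psa_density": (0.49, 0.58)},
    "T3b": {"age": (68.46, 7.01), "tPSA": (29.88, 33.92),
            "fPSA_ratio": (0.11, 0.10), "trus_volume": (49.50, 19.86),
            "psa_density": (0.50, 0.51)},
    "healthy": {"age": (64.0, 8.0), "tPSA": (1.5, 1.0),
                "fPSA_ratio": (0.25, 0.08), "trus_volume": (30.0, 10.0),
                "psa_density": (0.05, 0.03)},
}
#: Gleason (primary+secondary) category counts per stage.
GLEASON_COUNTS = {
    "T2c": {"3+3": 2, "3+4": 7, "4+3": 14, ">=8": 12},
    "T3b": {"3+3": 1, "3+4": 3, "4+3": 5, ">=8": 4},
}

#: Stage-dependent true refill parameters (A, beta).
TIC_TRUTH = {"healthy": (0.8, 0.40), "T2c": (1.0, 0.50), "T3b": (1.3, 0.70)}


@dataclass(frozen=True)
class StudyConfig:
    """Knobs of the synthetic study; defaults mirror the study cohort."""

    n_healthy: int = 22
    n_T2c: int = 35
    n_T3b: int = 13
    image_size: int = 128
    texture_contrast: float = 1.5
    de_log2fc: float = 1.5
    n_planted_de: int = 30
    nb_dispersion: float = 0.2
    tic_noise_sd: float = 0.05
    n_mrna: int = 600
    n_mirna: int = 200
    seed: int = 0

    def __post_init__(self):
        if min(self.n_healthy, self.n_T2c, self.n_T3b) < 1:
            raise ValueError("all group sizes must be >= 1")
        if self.image_size < 32 or self.image_size % 4:
            raise ValueError("image_size must be >= 32 and divisible by 4")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")

    def subjects(self) -> pd.DataFrame:
        rows = []
        for group, n, tag in (("healthy", self.n_healthy, "H"),
                              ("T2c", self.n_T2c, "T2C"),
                              ("T3b", self.n_T3b, "T3B")):
            rows += [{"subject_id": f"{tag}{k + 1:03d}", "group": group}
                     for k in range(n)]
        return pd.DataFrame(rows).set_index("subject_id")


def _rng(cfg: StudyConfig, stream: int) -> np.random.Generator:
    # independent, seed-locked stream per generator
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

@dataclass
class SyntheticImage:
    subject_id: str
    group: str
    modality: str  # "Bmode" or "CEUS-peak"
    image: np.ndarray  # float, [0, 255] scale
    mask: np.ndarray  # bool


def _ellipse_mask(size: int) -> np.ndarray:
    c = (size - 1) / 2.0
    a, b = size * 0.28, size * 0.20
    yy, xx = np.mgrid[0:size, 0:size]
    mask = ((yy - c) / b) ** 2 + ((xx - c) / a) ** 2 <= 1.0
    if mask.sum() < 100:
        raise ValueError("image_size too small for a >= 100-pixel elliptical ROI")
    return mask

# texture knobs: speckle correlation length and deviation gain per stage,
# both scaled by texture_contrast (0 -> all stages identical)
_GROUP_TEXTURE_OFFSET = {"healthy": 0.0, "T2c": 0.5, "T3b": 1.0}


def _speckle(rng, size, shape_k, sigma):
    field = rng.gamma(shape=shape_k, scale=1.0 / shape_k, size=(size, size))
    if sigma > 0:
        field = ndimage.gaussian_filter(field, sigma, mode="wrap")
    return field


def gen_images(cfg: StudyConfig) -> list[SyntheticImage]:
    """One (B-mode, CEUS-peak) image pair with a shared ROI per subject."""
    rng = _rng(cfg, 1)
    size = cfg.image_size
    mask = _ellipse_mask(size)
    out: list[SyntheticImage] = []
    subjects = cfg.subjects()
    for sid, row in subjects.iterrows():
        off = _GROUP_TEXTURE_OFFSET[row["group"]] * cfg.texture_contrast
        for modality, base in (("Bmode", 90.0), ("CEUS-peak", 130.0)):
            background = base + 25.0 * ndimage.gaussian_filter(
                rng.standard_normal((size, size)), size / 8.0, mode="wrap")
            # out-of-ROI speckle: fine-grained; in-ROI speckle: coarser and
            # stronger with stage, which is what texture features detect
            spk_out = _speckle(rng, size, shape_k=4.0, sigma=0.6)
            spk_in = _speckle(rng, size, shape_k=4.0, sigma=0.6 + 0.5 * off)
            spk_in = 1.0 + (1.0 + 0.30 * off) * (spk_in - 1.0)
            speckle = np.where(mask, spk_in, spk_out)
            img = np.clip(background * speckle * (1.0 + 0.15 * mask), 0.0, 255.0)
            out.append(SyntheticImage(subject_id=sid, group=row["group"],
                                      modality=modality, image=img, mask=mask))
    return out


# ---------------------------------------------------------------------------
# TICs
# ---------------------------------------------------------------------------

def gen_tics(cfg: StudyConfig) -> tuple[dict[str, TICurve], pd.DataFrame]:
    """Refill curves (40 points over 12 s) and the true (A, beta) table."""
    rng = _rng(cfg, 2)
    t = np.linspace(0.0, 12.0, 40)
    curves: dict[str, TICurve] = {}
    truth_rows = []
    for sid, row in cfg.subjects().iterrows():
        a0, b0 = TIC_TRUTH[row["group"]]
        a = a0 * rng.uniform(0.9, 1.1)
        b = b0 * rng.uniform(0.9, 1.1)
        clean = a * (1.0 - np.exp(-b * t))
        noise = rng.normal(0.0, cfg.tic_noise_sd * a, size=t.size) \
            if cfg.tic_noise_sd > 0 else 0.0
        curves[sid] = TICurve(t, clean + noise, subject_id=sid)
        truth_rows.append({"subject_id": sid, "A": a, "beta": b})
    return curves, pd.DataFrame(truth_rows).set_index("subject_id")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _nb_draw(rng, mu, dispersion):
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def gen_expression(cfg: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(mrna_counts, mirna_counts, truth_table) with all planted effects.

    Planted structure: ``n_planted_de`` T2c-specific and T3b-specific DE
    features per modality split, the six-biomarker panel at
    |log2FC| = de_log2fc between T2c and T3b, twelve monotonically
    decreasing mRNAs and six monotonically increasing miRNAs along
    healthy -> T2c -> T3b.
    """
    rng = _rng(cfg, 3)
    subjects = cfg.subjects()
    groups = subjects["group"]

    def feature_names(prefix, n, special):
        generic = [f"{prefix}{k + 1:04d}" for k in range(n - len(special))]
        return list(special) + generic

    special_mrna = list(BIOMARKER_MRNAS) + list(MONOTONE_DEC_GENES)
    special_mirna = list(BIOMARKER_MIRNAS) + list(MONOTONE_INC_MIRNAS)
    if cfg.n_mrna < len(special_mrna) + 2 * cfg.n_planted_de:
        raise ValueError("n_planted_de exceeds available mRNA features")
    if cfg.n_mirna < len(special_mirna) + 2 * cfg.n_planted_de // 3:
        raise ValueError("n_planted_de exceeds available miRNA features")
    mrna_ids = feature_names("GENE", cfg.n_mrna, special_mrna)
    mirna_ids = feature_names("miR-x", cfg.n_mirna, special_mirna)

    fold = 2.0 ** cfg.de_log2fc
    half = 2.0 ** (cfg.de_log2fc / 2.0)
    truth_rows: list[dict] = []

    def build(ids, modality, n_spec_de):
        n = len(ids)
        base = rng.lognormal(mean=4.5, sigma=1.0, size=n) + 5.0
        mult = pd.DataFrame(1.0, index=ids, columns=GROUPS)
        # biomarkers: T3b vs T2c directions at the full planted fold change
        panel = BIOMARKER_MRNAS if modality == "mRNA" else BIOMARKER_MIRNAS
        for name in panel:
            d = BIOMARKER_DIRECTIONS[name]
            mult.loc[name, "T3b"] = fold if d == "up" else 1.0 / fold
            truth_rows.append({"feature": name, "modality": modality,
                               "effect": "biomarker", "direction": d,
                               "log2fc": cfg.de_log2fc if d == "up" else -cfg.de_log2fc})
        # monotone trends
        mono = MONOTONE_DEC_GENES if modality == "mRNA" else MONOTONE_INC_MIRNAS
        step = 1.0 / half if modality == "mRNA" else half
        direc = "decreasing" if modality == "mRNA" else "increasing"
        for name in mono:
            mult.loc[name, "T2c"] *= step
            mult.loc[name, "T3b"] *= step * step
            truth_rows.append({"feature": name, "modality": modality,
                               "effect": f"monotone_{direc[:3]}", "direction": direc,
                               "log2fc": np.log2(step)})
        # stage-specific DE vs healthy on generic features
        generic = [i for i in ids if i not in set(panel) | set(mono)]
        chosen = rng.choice(len(generic), size=2 * n_spec_de, replace=False)
        signs = rng.choice([1.0, -1.0], size=2 * n_spec_de)
        for k, (idx, sgn) in enumerate(zip(chosen, signs)):
            name = generic[idx]
            stage = "T2c" if k < n_spec_de else "T3b"
            mult.loc[name, stage] = fold**sgn
            truth_rows.append({"feature": name, "modality": modality,
                               "effect": f"{stage}_specific",
                               "direction": "up" if sgn > 0 else "down",
                               "log2fc": sgn * cfg.de_log2fc})
        # draw counts with per-sample depth variation
        depth = rng.uniform(0.7, 1.3, size=len(subjects))
        counts = np.empty((n, len(subjects)), dtype=np.int64)
        mu_groups = {g: base * mult[g].to_numpy() for g in GROUPS}
        for s_idx, (sid, grp) in enumerate(groups.items()):
            counts[:, s_idx] = _nb_draw(rng, mu_groups[grp] * depth[s_idx],
                                        cfg.nb_dispersion)
        return pd.DataFrame(counts, index=ids, columns=subjects.index)

    mrna = build(mrna_ids, "mRNA", cfg.n_planted_de)
    mirna = build(mirna_ids, "miRNA", max(cfg.n_planted_de // 3, 1))
    truth = pd.DataFrame(truth_rows)
    return mrna, mirna, truth


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

def _trunc_normal(rng, mean, sd, n):
    if sd == 0:
        return np.full(n, float(mean))
    a = (0.0 - mean) / sd  # truncate at 0
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def gen_clinical(cfg: StudyConfig) -> pd.DataFrame:
    """Truncated-normal clinical covariates from the per-group moments."""
    rng = _rng(cfg, 4)
    subjects = cfg.subjects()
    cols = {c: np.empty(len(subjects)) for c in
            ("age", "tPSA", "fPSA_ratio", "trus_volume", "psa_density")}
    gleason = []
    for group in GROUPS:
        sel = (subjects["group"] == group).to_numpy()
        n = int(sel.sum())
        for cov, (mean, sd) in CLINICAL_MOMENTS[group].items():
            cols[cov][sel] = _trunc_normal(rng, mean, sd, n)
        if group in GLEASON_COUNTS:
            cats, weights = zip(*GLEASON_COUNTS[group].items())
            probs = np.array(weights, dtype=float)
            gl = rng.choice(cats, size=n, p=probs / probs.sum())
        else:
            gl = np.full(n, "none", dtype=object)
        gleason.extend(gl.tolist())
    out = subjects.copy()
    for cov, vals in cols.items():
        out[cov] = vals
    out["gleason"] = gleason
    return out


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------

def gen_interactions(cfg: StudyConfig, n_decoys: int = 30) -> pd.DataFrame:
    """Planted miRNA -> gene edge list: 4 hubs covering 9 targets + decoys.

    Hubs are the first four monotone-increasing miRNAs with out-degrees
    (3, 2, 2, 2) over nine distinct decreasing target genes.  Decoys are
    degree-1 edges from the remaining increasing miRNAs and random edges
    among generic (non-monotone) features, which the trend filter removes.
    """
    rng = _rng(cfg, 5)
    edges = []
    pos = 0
    for hub, deg in zip(HUB_MIRNAS, _HUB_DEGREES):
        for g in TARGET_GENES[pos:pos + deg]:
            edges.append({"mirna": hub, "gene": g})
        pos += deg
    for decoy in MONOTONE_INC_MIRNAS[4:]:
        g = TARGET_GENES[int(rng.integers(len(TARGET_GENES)))]
        edges.append({"mirna": decoy, "gene": g})
    for _ in range(n_decoys):
        m = f"miR-x{int(rng.integers(1, cfg.n_mirna)):04d}"
        g = f"GENE{int(rng.integers(1, cfg.n_mrna)):04d}"
        edges.append({"mirna": m, "gene": g})
    return pd.DataFrame(edges)


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    config: StudyConfig
    images: list[SyntheticImage]
    tics: dict[str, TICurve]
    tic_truth: pd.DataFrame
    mrna_counts: pd.DataFrame
    mirna_counts: pd.DataFrame
    expression_truth: pd.DataFrame
    clinical: pd.DataFrame
    interactions: pd.DataFrame

    @property
    def groups(self) -> pd.Series:
        return self.clinical["group"]


def generate_study(cfg: StudyConfig, with_images: bool = True) -> SyntheticStudy:
    """Generate the complete synthetic study from one seeded config."""
    tics, tic_truth = gen_tics(cfg)
    mrna, mirna, truth = gen_expression(cfg)
    return SyntheticStudy(
        config=cfg,
        images=gen_images(cfg) if with_images else [],
        tics=tics,
        tic_truth=tic_truth,
        mrna_counts=mrna,
        mirna_counts=mirna,
        expression_truth=truth,
        clinical=gen_clinical(cfg),
        interactions=gen_interactions(cfg),
    )
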