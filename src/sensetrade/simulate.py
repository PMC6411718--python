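"""Seeded synthetic data with the statistical structure the analyses assume.

The generators emulate a genus-wide comparative study: a pure-birth
phylogeny of ~62 species, continuous traits evolved under λ-transformed
Brownian motion, binary traits from a latent-threshold model (so they carry
tunable phylogenetic signal), specimen-level morphometric tables in which
eye and funiculus areas scale isometrically with head size while the EF
ratio varies independently of size, and a two-group imaginal-disc dataset
whose disc ratios correlate with adult EF ratios.

Every generator is a pure function of its arguments: a single master seed
plus a fixed per-generator offset selects an independent substream, so
adding one generator never perturbs the draws of another.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .morphometrics import SPECIMEN_COLUMNS
from .phylo import PhyloCov, Phylogeny, lambda_transform

__all__ = [
    "SyntheticConfig",
    "simulate_tree",
    "simulate_bm_trait",
    "simulate_binary_trait",
    "simulate_pgls_dataset",
    "simulate_morphometric_table",
    "simulate_disc_data",
    "simulate_bundle",
]

# fixed substream offsets (never renumber; append only)
_OFF_TREE = 11
_OFF_BM = 12
_OFF_BINARY = 13
_OFF_PGLS = 14
_OFF_MORPHO = 15
_OFF_DISC = 16

# reference morphology (µm), loosely a mid-sized drosophilid:
# head width 0.36 x body length; eye height 1.2 x eye width;
# funiculus length 1.5 x funiculus width
_HEAD_FRAC = 0.36
_EYE_ASPECT = 1.2
_FUN_ASPECT = 1.5
_REF_BODY = 2500.0
_REF_EYE_WIDTH = 350.0
_REF_FUN_WIDTH = 100.0


def _eye_area_from_width(w: np.ndarray) -> np.ndarray:
    # r = (w + 1.2w/2)/2 = 0.8w for the fixed aspect; area = 2*pi*r^2
    return 2.0 * math.pi * (0.8 * w) ** 2


def _eye_width_from_area(a: np.ndarray) -> np.ndarray:
    return np.sqrt(a / (2.0 * math.pi)) / 0.8


def _fun_area_from_width(w: np.ndarray) -> np.ndarray:
    # r = (1.5w/2 + w/2)/2 = 0.625w; area = 4*pi*r^2 - pi*(w/2)^2 = 1.5*pi*w^2
    return 1.5 * math.pi * w ** 2


def _fun_width_from_area(a: np.ndarray) -> np.ndarray:
    return np.sqrt(a / (1.5 * math.pi))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for the full synthetic study.

    Defaults mirror the design being emulated: 62 species, 5 replicate
    specimens each, strict Brownian trait evolution on a unit-depth
    pure-birth tree, isometric (slope-2) area scaling, and an
    allocation axis whose log-scale spread makes EF ratios vary several
    fold independently of size.
    """

    seed: int = 0
    n_species: int = 62
    birth_rate: float = 1.0
    sigma2: float = 1.0
    lambda_true: float = 1.0
    beta_true: tuple = (1.0, 0.5)
    binary_prevalence: float = 0.35
    isometry_slope: float = 2.0
    ef_log_sd: float = 0.45
    body_log_sd: float = 0.30
    n_replicates_per_species: int = 5
    measurement_cv: float = 0.03

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        for name in ("birth_rate", "sigma2", "ef_log_sd", "body_log_sd", "measurement_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.binary_prevalence < 1.0:
            raise ValueError("binary_prevalence must be in (0, 1)")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must be in [0, 1]")
        if self.n_replicates_per_species < 1:
            raise ValueError("need at least one replicate per species")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["beta_true"] = list(self.beta_true)
        return d


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(offset)])


def _tip_labels(n: int) -> list:
    width = len(str(n))
    return [f"s{i + 1:0{width}d}" for i in range(n)]


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0,
                  unit_depth: bool = True) -> Phylogeny:
    """Pure-birth (Yule) tree: exponential waiting times, uniform splitting.

    Ultrametric by construction; rescaled to unit root-to-tip depth by
    default so Brownian rates are comparable across runs.
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = _rng(seed, _OFF_TREE)
    root = {"birth": 0.0, "children": []}
    active = []
    for _ in range(2):
        child = {"birth": 0.0, "children": []}
        root["children"].append(child)
        active.append(child)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = active.pop(int(rng.integers(k)))
        node["split"] = t
        kids = [{"birth": t, "children": []}, {"birth": t, "children": []}]
        node["children"] = kids
        active.extend(kids)
    total = t + rng.exponential(1.0 / (birth_rate * n_tips))
    scale = 1.0 / total if unit_depth else 1.0

    labels = iter(_tip_labels(n_tips))

    def newick(node: dict) -> str:
        end = node.get("split", total)
        length = (end - node["birth"]) * scale
        if node["children"]:
            inner = ",".join(newick(c) for c in node["children"])
            return f"({inner}):{length:.12g}"
        return f"{next(labels)}:{length:.12g}"

    inner = ",".join(newick(c) for c in root["children"])
    return Phylogeny.from_newick(f"({inner});")


def _mvn_on_tree(tree: Phylogeny, sigma2: float, lam: float, root: float,
                 rng: np.random.Generator) -> pd.Series:
    tips = list(tree.tips)
    n = len(tips)
    if sigma2 == 0.0:
        return pd.Series(np.full(n, float(root)), index=tips)
    W = lambda_transform(tree.vcv(), lam).matrix
    L = np.linalg.cholesky(sigma2 * W + 1e-12 * np.eye(n))
    return pd.Series(root + L @ rng.standard_normal(n), index=tips)


def simulate_bm_trait(tree: Phylogeny, sigma2: float = 1.0, lambda_true: float = 1.0,
                      root: float = 0.0, seed: int = 0) -> pd.Series:
    """One draw from N(root·1, sigma2·V(λ)) via Cholesky factorization."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    return _mvn_on_tree(tree, sigma2, lambda_true, root, _rng(seed, _OFF_BM))


def simulate_binary_trait(tree: Phylogeny, prevalence: float = 0.35,
                          lambda_true: float = 1.0, seed: int = 0) -> pd.Series:
    """Latent-threshold binary trait with tunable phylogenetic signal.

    A latent Brownian trait is thresholded at its (1 − prevalence)
    empirical quantile, so round(n·prevalence) species score 1.  An iid
    Bernoulli would carry no signal; the latent construction inherits the
    tree structure of the Brownian model.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    latent = _mvn_on_tree(tree, 1.0, lambda_true, 0.0, _rng(seed, _OFF_BINARY))
    n = len(latent)
    k = int(round(n * prevalence))
    out = pd.Series(np.zeros(n), index=latent.index)
    if k > 0:
        top = latent.to_numpy().argsort()[::-1][:k]
        out.iloc[top] = 1.0
    return out


def simulate_pgls_dataset(tree: Phylogeny, beta_true=(1.0, 0.5),
                          lambda_resid: float = 1.0, sigma2: float = 1.0,
                          binary_prevalence: float = 0.35, seed: int = 0):
    """Response + design matrix for PGLS recovery experiments.

    X = [1, binary predictor]; y = Xβ + ε with ε ~ N(0, sigma2·V(λ_resid)).
    Returns ``(y, X)`` keyed by species.
    """
    beta = np.asarray(beta_true, dtype=float)
    if beta.size != 2:
        raise ValueError("beta_true must be (intercept, slope)")
    b = simulate_binary_trait(tree, binary_prevalence, 1.0, seed=seed)
    eps = _mvn_on_tree(tree, sigma2, lambda_resid, 0.0, _rng(seed, _OFF_PGLS))
    X = pd.DataFrame({"const": 1.0, "predictor": b})
    y = pd.Series(X.to_numpy() @ beta, index=X.index) + eps
    return y.rename("response"), X


def simulate_morphometric_table(config: SyntheticConfig, tree: Phylogeny):
    """Specimen-level measurement table with isometric size scaling.

    Log body length evolves by Brownian motion on the tree; head width is
    proportional to body length.  A latent Brownian "allocation axis" z
    (variance ``ef_log_sd²``) moves log eye area by +z/2 and log funiculus
    area by −z/2, so log EF ratio equals z and is independent of size by
    construction.  Linear eye/funiculus
    measurements are back-solved through the exact inverses of the surface
    formulas at fixed aspect ratios, then replicate noise is applied
    multiplicatively (log-normal, coefficient of variation
    ``measurement_cv``) to every linear measurement.

    Returns ``(specimens, truth)``: the specimen DataFrame (CSV layout) and
    a per-species table of the noiseless quantities (body, head, areas,
    ef_ratio, allocation z) for round-trip checks.
    """
    rng = _rng(config.seed, _OFF_MORPHO)
    tips = list(tree.tips)
    n = len(tips)
    log_body = np.log(_REF_BODY) + _mvn_on_tree(
        tree, config.body_log_sd ** 2, 1.0, 0.0, rng).to_numpy()
    z = _mvn_on_tree(tree, config.ef_log_sd ** 2, 1.0, 0.0, rng).to_numpy()
    body = np.exp(log_body)
    head = _HEAD_FRAC * body
    ref_head = _HEAD_FRAC * _REF_BODY
    rel = config.isometry_slope * (np.log(head) - math.log(ref_head))
    eye_area = _eye_area_from_width(np.full(n, _REF_EYE_WIDTH)) * np.exp(rel + z / 2.0)
    fun_area = _fun_area_from_width(np.full(n, _REF_FUN_WIDTH)) * np.exp(rel - z / 2.0)
    eye_w = _eye_width_from_area(eye_area)
    fun_w = _fun_width_from_area(fun_area)

    rows = []
    cv = config.measurement_cv
    for i, sp in enumerate(tips):
        for r in range(config.n_replicates_per_species):
            noise = np.exp(rng.normal(0.0, cv, size=6)) if cv > 0 else np.ones(6)
            rows.append({
                "species": sp,
                "replicate": f"r{r + 1}",
                "body_length": body[i] * noise[0],
                "head_width": head[i] * noise[1],
                "eye_width": eye_w[i] * noise[2],
                "eye_height": _EYE_ASPECT * eye_w[i] * noise[3],
                "funiculus_length": _FUN_ASPECT * fun_w[i] * noise[4],
                "funiculus_width": fun_w[i] * noise[5],
            })
    specimens = pd.DataFrame(rows, columns=SPECIMEN_COLUMNS)
    truth = pd.DataFrame({
        "species": tips, "body_length": body, "head_width": head,
        "eye_area": eye_area, "funiculus_area": fun_area,
        "ef_ratio": eye_area / fun_area, "allocation_z": z,
    })
    return specimens, truth


def simulate_disc_data(n_species: int = 30, group_means=(1.3, 2.6), sd: float = 0.12,
                       rho_adult: float = 0.8, seed: int = 0, n_replicates: int = 8):
    """Two-group imaginal-disc ratios with copula-linked adult EF ratios.

    Species fall into an olfactory-biased and a visually-biased group of
    disc (eye:antenna) ratios: log disc ratio = log(group mean) + sd·u.
    Adult EF ratios follow a bivariate-normal copula on the log scale with
    correlation ``rho_adult`` against the standardized total log disc
    ratio (group separation included), so the population log-log Pearson
    correlation equals ``rho_adult``.

    Returns ``(discs, adult_ef)``: replicate-level disc measurements (CSV
    layout) and the per-species adult EF ratio series.
    """
    if not (group_means[0] > 0 and group_means[1] > 0):
        raise ValueError("group means must be positive")
    if not -1.0 <= rho_adult <= 1.0:
        raise ValueError("|rho_adult| must be <= 1")
    rng = _rng(seed, _OFF_DISC)
    tips = _tip_labels(n_species)
    group = rng.integers(0, 2, size=n_species)
    mu = np.log(np.asarray(group_means, dtype=float))[group]
    u = rng.standard_normal(n_species)
    w = rng.standard_normal(n_species)
    log_disc = mu + sd * u
    # theoretical moments of the equal-weight mixture
    m_tot = float(np.mean(np.log(group_means)))
    v_tot = 0.25 * (math.log(group_means[1] / group_means[0])) ** 2 + sd ** 2
    z_disc = (log_disc - m_tot) / math.sqrt(v_tot)
    sd_ef = 0.5  # log-scale spread of adult EF ratios
    log_ef = math.log(8.0) + sd_ef * (rho_adult * z_disc
                                      + math.sqrt(1.0 - rho_adult ** 2) * w)
    adult_ef = pd.Series(np.exp(log_ef), index=tips, name="ef_ratio")

    rows = []
    base_antenna = 5000.0  # µm², antennal portion scale
    for i, sp in enumerate(tips):
        for r in range(n_replicates):
            rep_noise = np.exp(rng.normal(0.0, 0.05, size=2))
            antennal = base_antenna * rep_noise[0]
            rows.append({
                "species": sp, "replicate": f"r{r + 1}",
                "eye_portion_area": antennal * math.exp(log_disc[i]) * rep_noise[1],
                "antennal_portion_area": antennal,
            })
    discs = pd.DataFrame(
        rows, columns=["species", "replicate", "eye_portion_area", "antennal_portion_area"])
    return discs, adult_ef


def simulate_bundle(config: SyntheticConfig, out_dir) -> dict:
    """Write a complete synthetic study to ``out_dir``.

    Files: ``tree.nwk``, ``specimens.csv``, ``traits.csv`` (per-species
    binary traits, coupled to the allocation axis so they correlate with
    the EF ratio), ``discs.csv`` and ``config.json``.  Returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(config.n_species, config.birth_rate, config.seed)
    specimens, truth = simulate_morphometric_table(config, tree)

    # binary traits: latent = allocation axis + independent Brownian noise,
    # thresholded at prevalence -> correlated with EF but not deterministic
    z = pd.Series(truth.allocation_z.to_numpy(), index=truth.species)
    binaries = {}
    for j, name in enumerate(
            ["wing_pigmentation_female", "wing_pigmentation_male", "light_courtship"]):
        noise = _mvn_on_tree(tree, config.ef_log_sd ** 2, 1.0, 0.0,
                             _rng(config.seed, 100 + j))
        latent = z + noise
        k = int(round(len(latent) * config.binary_prevalence))
        col = pd.Series(np.zeros(len(latent)), index=latent.index)
        col.iloc[latent.to_numpy().argsort()[::-1][:k]] = 1.0
        binaries[name] = col.astype(int)
    traits = pd.DataFrame(binaries)
    traits.index.name = "species"

    discs, _ = simulate_disc_data(
        n_species=config.n_species, seed=config.seed)

    paths = {
        "tree": out / "tree.nwk",
        "specimens": out / "specimens.csv",
        "traits": out / "traits.csv",
        "discs": out / "discs.csv",
        "config": out / "config.json",
    }
    paths["tree"].write_text(tree.to_newick() + "\n")
    specimens.to_csv(paths["specimens"], index=False, float_format="%.6g")
    traits.to_csv(paths["traits"])
    discs.to_csv(paths["discs"], index=False, float_format="%.6g")
    paths["config"].write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
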