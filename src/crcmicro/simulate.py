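"""Synthetic cohorts with planted, recoverable structure.

The source cohorts (Finnish population surveys with shallow-shotgun gut
metagenomes and register-based cancer follow-up) are not publicly
downloadable, so this module generates stand-in data whose marginals match
the published participant characteristics and whose microbiome and
survival outcomes carry *known* planted effects:

* lifestyle variables drawn with realistic marginals (median age ~48,
  46% men, median BMI ~26, ...); BMI and waist circumference share a
  0.85 correlation so the body-fatness averaging path is exercised;
* a species count table in which a chosen set of taxa shifts log-linearly
  with the lifestyle index (mimicking the reported Lachnospiraceae-up /
  Bifidobacterium-down pattern for high-risk lifestyles) and community
  evenness is calibrated so the true Shannon-vs-index slope equals a
  requested value;
* a random rooted phylogeny in which co-varying planted taxa are
  clade-mates;
* survival times with a planted log-hazard per index point and
  administrative censoring, singly or as a multi-cohort family for
  meta-analysis.

Every stage derives its own child seed deterministically from the single
master seed, so identical configurations reproduce bit-identical data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import skbio

from .errors import AlignmentError, ConfigurationError
from .prep import FeatureTable

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Default per-variable marginal parameters, chosen to match the published
#: cohort characteristics (medians/IQRs and category proportions).
DEFAULT_MARGINALS: dict = {
    "age": {"mean": 48.0, "sd": 13.0, "min": 25.0, "max": 74.0},
    "height_woman": {"mean": 163.0, "sd": 6.0},
    "height_man": {"mean": 176.0, "sd": 7.0},
    "bmi": {"mean": 26.5, "sd": 4.5, "min": 16.0},
    "wc_woman": {"mean": 83.0, "sd": 12.0},
    "wc_man": {"mean": 95.5, "sd": 11.0},
    "bmi_wc_corr": 0.85,
    "activity_probs": {"inactive": 0.19, "moderate": 0.50, "active": 0.31},
    "whole_grains": {"shape": 1.6, "scale": 38.0},
    "dairy": {"shape": 2.2, "scale": 190.0},
    "red_meat": {"shape": 1.3, "scale": 230.0},
    "processed_meat": {"shape": 1.0, "scale": 260.0},
    "alcohol": {"p_zero": 0.25, "shape": 0.9, "scale": 12.0},
    "energy": {"mean": 7.8, "sd": 2.4, "min": 2.0},
    "p_smoker": 0.24,
    "p_medication": 0.086,
}


@dataclass(frozen=True)
class PlantedTaxon:
    """A taxon whose log abundance shifts with the lifestyle index."""

    taxon_id: str
    lfc: float                  # log-fold-change per index point
    cluster: int | None = None  # co-occurrence block label

    @property
    def direction(self) -> str:
        return "up" if self.lfc > 0 else "down"


def default_planted_taxa() -> list[PlantedTaxon]:
    """Five index-negative taxa (one co-occurrence block, mimicking the
    Lachnospiraceae pattern) and three index-positive taxa (a second
    block, mimicking Bifidobacterium)."""
    neg = [PlantedTaxon(f"sp{i:04d}", -1.0, cluster=1) for i in range(1, 6)]
    pos = [PlantedTaxon(f"sp{i:04d}", +1.0, cluster=2) for i in range(6, 9)]
    return neg + pos


@dataclass
class SimulationConfig:
    """Free parameters of the synthetic cohort generator.

    Defaults are the study conditions: a 1,228-participant cohort with
    46% men, library sizes between 50,000 and 900,000 reads, a planted
    Shannon slope of 0.05 per index point and a planted hazard ratio of
    0.81 per index point.
    """

    n_participants: int = 1228
    n_species: int = 150
    seed: int = 0
    frac_men: float = 0.46
    lifestyle_marginals: dict = field(default_factory=dict)
    diversity_effect: float = 0.05
    planted_taxa: list[PlantedTaxon] = field(
        default_factory=default_planted_taxa)
    depth_range: tuple[int, int] = (50_000, 900_000)
    hazard_log_hr: float = math.log(0.81)
    baseline_hazard: float = 0.004
    censor_time: float = 16.0
    n_cohorts: int = 5
    heterogeneity_sd: float = 0.0   # between-cohort SD of the log-hazard
    shannon_base: float | None = None  # default 0.6 * ln(n_species)
    shannon_noise_sd: float = 0.3   # biological scatter of per-sample entropy
    cluster_sd: float = 0.5         # shared within-block log-abundance SD
    taxon_sd: float = 1.5           # between-taxa baseline log-abundance SD
    noise_sd: float = 0.7           # per-sample idiosyncratic log SD

    def __post_init__(self):
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be positive")
        if self.n_species <= 0:
            raise ConfigurationError("n_species must be positive")
        if not 0 <= self.frac_men <= 1:
            raise ConfigurationError("frac_men must lie in [0, 1]")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("depth_range must satisfy 1 <= lo <= hi")
        if self.n_species < len(self.planted_taxa):
            raise ConfigurationError(
                "n_species smaller than the number of planted taxa")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if self.censor_time <= 0:
            raise ConfigurationError("censor_time must be positive")
        if self.n_cohorts <= 0:
            raise ConfigurationError("n_cohorts must be positive")
        if self.heterogeneity_sd < 0:
            raise ConfigurationError("heterogeneity_sd must be >= 0")
        if self.shannon_noise_sd < 0:
            raise ConfigurationError("shannon_noise_sd must be >= 0")
        marg = dict(DEFAULT_MARGINALS)
        marg.update(self.lifestyle_marginals)
        probs = marg["activity_probs"]
        if any(not 0 <= p <= 1 for p in probs.values()) or \
                abs(sum(probs.values()) - 1) > 1e-9:
            raise ConfigurationError("activity_probs must be a distribution")
        for key in ("p_smoker", "p_medication"):
            if not 0 <= marg[key] <= 1:
                raise ConfigurationError(f"{key} must lie in [0, 1]")
        if not -1 <= marg["bmi_wc_corr"] <= 1:
            raise ConfigurationError("bmi_wc_corr must lie in [-1, 1]")
        self._marginals = marg

    def child_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the master seed."""
        stage_key = int.from_bytes(stage.encode(), "little") % (2 ** 31)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed,
                                   spawn_key=(stage_key,)))


@dataclass
class GroundTruth:
    """Planted structure of one synthetic dataset."""

    index_latent: dict[str, float]       # participant id -> index used
    planted_taxa: list[PlantedTaxon]
    diversity_effect: float
    hazard_log_hr: float | None = None

    def to_json(self, path) -> None:
        payload = {
            "index_latent": self.index_latent,
            "planted_taxa": [asdict(t) for t in self.planted_taxa],
            "diversity_effect": self.diversity_effect,
            "hazard_log_hr": self.hazard_log_hr,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _truncated_normal(rng, n, mean, sd, lo=None, hi=None):
    x = rng.normal(mean, sd, size=n)
    if lo is not None or hi is not None:
        x = np.clip(x, lo, hi)
    return x


def generate_phenotypes(config: SimulationConfig) -> pd.DataFrame:
    """Draw a phenotype table with realistic lifestyle marginals.

    Variables are independent across participants and (except for the
    planted BMI-WC correlation) across variables; heights are drawn
    sex-specifically so tertile scoring is meaningful.
    """
    rng = config.child_rng("phenotypes")
    n = config.n_participants
    m = config._marginals

    sex = np.where(rng.random(n) < config.frac_men, "man", "woman")
    age = _truncated_normal(rng, n, m["age"]["mean"], m["age"]["sd"],
                            m["age"]["min"], m["age"]["max"])

    height = np.empty(n)
    for s, key in (("woman", "height_woman"), ("man", "height_man")):
        mask = sex == s
        height[mask] = rng.normal(m[key]["mean"], m[key]["sd"], mask.sum())

    rho = m["bmi_wc_corr"]
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    bmi = np.maximum(m["bmi"]["mean"] + m["bmi"]["sd"] * z[:, 0],
                     m["bmi"]["min"])
    wc_mean = np.where(sex == "man", m["wc_man"]["mean"], m["wc_woman"]["mean"])
    wc_sd = np.where(sex == "man", m["wc_man"]["sd"], m["wc_woman"]["sd"])
    wc = np.maximum(wc_mean + wc_sd * z[:, 1], 50.0)

    levels = list(m["activity_probs"])
    activity = rng.choice(levels, size=n, p=[m["activity_probs"][k]
                                             for k in levels])
    whole_grains = rng.gamma(m["whole_grains"]["shape"],
                             m["whole_grains"]["scale"], n)
    dairy = rng.gamma(m["dairy"]["shape"], m["dairy"]["scale"], n)
    red_meat = rng.gamma(m["red_meat"]["shape"], m["red_meat"]["scale"], n)
    processed_meat = rng.gamma(m["processed_meat"]["shape"],
                               m["processed_meat"]["scale"], n)
    alcohol = rng.gamma(m["alcohol"]["shape"], m["alcohol"]["scale"], n)
    alcohol[rng.random(n) < m["alcohol"]["p_zero"]] = 0.0
    energy = _truncated_normal(rng, n, m["energy"]["mean"], m["energy"]["sd"],
                               m["energy"]["min"])
    smoking = np.where(rng.random(n) < m["p_smoker"], "smoker", "nonsmoker")
    medication = rng.random(n) < m["p_medication"]

    ids = [f"P{i:05d}" for i in range(1, n + 1)]
    return pd.DataFrame({
        "sex": sex, "age": age, "bmi": bmi, "wc": wc, "height": height,
        "activity": activity, "whole_grains": whole_grains, "dairy": dairy,
        "red_meat": red_meat, "processed_meat": processed_meat,
        "alcohol": alcohol, "energy": energy, "smoking": smoking,
        "medication": medication,
    }, index=pd.Index(ids, name="participant_id"))


# ---------------------------------------------------------------------------
# Microbiome
# ---------------------------------------------------------------------------

def _default_taxonomy(taxon_ids, planted: list[PlantedTaxon]) -> pd.Series:
    """Synthetic lineage strings; planted blocks get family/genus labels
    echoing the taxa the real study highlighted."""
    planted_map = {t.taxon_id: t for t in planted}
    rows = {}
    for i, tid in enumerate(taxon_ids):
        t = planted_map.get(tid)
        if t is not None and t.lfc < 0:
            lineage = ("d__Bacteria;p__Bacillota;c__Clostridia;"
                       "o__Lachnospirales;f__Lachnospiraceae;"
                       f"g__Dorea;s__Dorea synthetica_{tid}")
        elif t is not None:
            lineage = ("d__Bacteria;p__Actinomycetota;c__Actinomycetes;"
                       "o__Bifidobacteriales;f__Bifidobacteriaceae;"
                       f"g__Bifidobacterium;s__Bifidobacterium "
                       f"syntheticum_{tid}")
        else:
            lineage = (f"d__Bacteria;p__p{i % 7};c__c{i % 11};o__o{i % 13};"
                       f"f__f{i % 17};g__g{i % 23};s__{tid}")
        rows[tid] = lineage
    return pd.Series(rows, name="taxonomy")


def _shannon_of_softmax(z: np.ndarray, s: float) -> float:
    logits = s * z
    logits = logits - logits.max()
    p = np.exp(logits)
    p /= p.sum()
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def _calibrate_concentration(z: np.ndarray, target_h: float) -> float:
    """Bisect the concentration s >= 0 such that the Shannon entropy of
    softmax(s*z) equals ``target_h`` (entropy decreases in s)."""
    lo, hi = 0.0, 1.0
    while _shannon_of_softmax(z, hi) > target_h and hi < 64:
        hi *= 2
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if _shannon_of_softmax(z, mid) > target_h:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _random_tree(taxon_ids, planted: list[PlantedTaxon],
                 rng) -> skbio.TreeNode:
    """Random rooted binary tree; planted co-occurrence blocks are joined
    first so their members end up as clade-mates."""

    def leaf(name):
        node = skbio.TreeNode(name=name)
        node.length = float(rng.exponential(0.2) + 0.01)
        return node

    def join(a, b):
        parent = skbio.TreeNode(children=[a, b])
        parent.length = float(rng.exponential(0.2) + 0.01)
        return parent

    def agglomerate(nodes):
        nodes = list(nodes)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            b = nodes.pop(j)
            a = nodes.pop(i)
            nodes.append(join(a, b))
        return nodes[0]

    clusters: dict[int, list] = {}
    for t in planted:
        if t.cluster is not None:
            clusters.setdefault(t.cluster, []).append(t.taxon_id)
    clustered = {tid for members in clusters.values() for tid in members}
    pool = [agglomerate([leaf(tid) for tid in members])
            for members in clusters.values()]
    pool += [leaf(tid) for tid in taxon_ids if tid not in clustered]
    root = agglomerate(pool)
    root.length = None
    return root


def generate_microbiome(
    phenotypes: pd.DataFrame,
    index_total: np.ndarray | pd.Series,
    config: SimulationConfig,
) -> tuple[FeatureTable, skbio.TreeNode, GroundTruth]:
    """Draw species counts, a phylogeny, and the planted ground truth.

    The per-sample latent log abundance is Gaussian with a shared
    within-block component (compound-symmetric correlation inside planted
    co-occurrence blocks) plus the planted index-linked shifts; a
    per-sample concentration parameter is then calibrated so the Shannon
    entropy of the expected composition follows
    ``shannon_base + diversity_effect * (index - mean index)`` exactly,
    and counts are multinomial draws at a library size uniform on
    ``depth_range``.
    """
    index_total = np.asarray(index_total, dtype=float)
    if index_total.shape[0] != len(phenotypes):
        raise AlignmentError("index scores do not match the phenotype rows")

    rng = config.child_rng("microbiome")
    n, k = len(phenotypes), config.n_species
    taxon_ids = [f"sp{i:04d}" for i in range(1, k + 1)]
    missing = [t.taxon_id for t in config.planted_taxa
               if t.taxon_id not in taxon_ids]
    if missing:
        raise ConfigurationError(f"planted taxa not in the table: {missing}")

    base = rng.normal(0.0, config.taxon_sd, size=k)
    z = base[None, :] + rng.normal(0.0, config.noise_sd, size=(n, k))

    clusters: dict[int, list[int]] = {}
    col = {tid: j for j, tid in enumerate(taxon_ids)}
    for t in config.planted_taxa:
        if t.cluster is not None:
            clusters.setdefault(t.cluster, []).append(col[t.taxon_id])
    for members in clusters.values():
        z[:, members] += rng.normal(0.0, config.cluster_sd, size=(n, 1))

    centered = index_total - index_total.mean()
    for t in config.planted_taxa:
        z[:, col[t.taxon_id]] += t.lfc * centered

    h_base = (config.shannon_base if config.shannon_base is not None
              else 0.6 * math.log(k))
    # index-independent biological scatter keeps the planted slope exact
    # in expectation while giving alpha diversity a realistic residual SD
    targets = np.clip(h_base + config.diversity_effect * centered
                      + rng.normal(0.0, config.shannon_noise_sd, size=n),
                      0.05, 0.98 * math.log(k))

    lo, hi = config.depth_range
    depths = rng.integers(lo, hi + 1, size=n)
    counts = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        s = _calibrate_concentration(z[i], targets[i])
        logits = s * z[i] - (s * z[i]).max()
        p = np.exp(logits)
        p /= p.sum()
        counts[i] = rng.multinomial(depths[i], p)

    table = FeatureTable(
        pd.DataFrame(counts, index=phenotypes.index.copy(),
                     columns=taxon_ids),
        taxonomy=_default_taxonomy(taxon_ids, config.planted_taxa),
        mode="counts",
    )
    tree = _random_tree(taxon_ids, config.planted_taxa,
                        config.child_rng("tree"))
    truth = GroundTruth(
        index_latent=dict(zip(phenotypes.index, index_total.tolist())),
        planted_taxa=list(config.planted_taxa),
        diversity_effect=config.diversity_effect,
    )
    return table, tree, truth


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def generate_survival(
    phenotypes: pd.DataFrame,
    index_total: np.ndarray | pd.Series,
    config: SimulationConfig,
    log_hr: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Add exponential survival times with administrative censoring.

    The hazard is ``baseline_hazard * exp(log_hr * index + small
    covariate terms)`` (a mild smoking and age dependence keeps the
    adjustment sets non-trivial); events past ``censor_time`` are
    censored there.
    """
    index_total = np.asarray(index_total, dtype=float)
    if index_total.shape[0] != len(phenotypes):
        raise AlignmentError("index scores do not match the phenotype rows")
    if log_hr is None:
        log_hr = config.hazard_log_hr
    if rng is None:
        rng = config.child_rng("survival")

    smoker = (phenotypes["smoking"].to_numpy() == "smoker").astype(float)
    age = phenotypes["age"].to_numpy(dtype=float)
    log_rate = (math.log(config.baseline_hazard)
                + log_hr * index_total
                + 0.2 * smoker + 0.01 * (age - age.mean()))
    raw = rng.exponential(1.0, size=len(phenotypes)) / np.exp(log_rate)
    out = phenotypes.copy()
    out["time"] = np.minimum(raw, config.censor_time)
    out["event"] = (raw <= config.censor_time).astype(int)
    return out


def generate_multicohort(config: SimulationConfig) -> list[pd.DataFrame]:
    """Independent cohorts sharing (or spreading around) the planted
    log-hazard, for two-stage meta-analysis.

    Each cohort's true log hazard is ``hazard_log_hr`` plus a Gaussian
    deviation with SD ``heterogeneity_sd``; the realized value is stored
    in ``table.attrs["true_log_hr"]``.
    """
    from .scoring import compute_index

    if config.n_cohorts < 2:
        raise ConfigurationError("meta-analysis needs at least 2 cohorts")
    het_rng = config.child_rng("heterogeneity")
    cohorts = []
    for c in range(config.n_cohorts):
        sub = SimulationConfig(**{**_public_fields(config),
                                  "seed": config.seed * 1000 + c + 1})
        pheno = generate_phenotypes(sub)
        scores = compute_index(pheno)
        log_hr = config.hazard_log_hr
        if config.heterogeneity_sd > 0:
            log_hr += het_rng.normal(0.0, config.heterogeneity_sd)
        table = generate_survival(pheno, scores["total"].to_numpy(), sub,
                                  log_hr=log_hr)
        table["index_total"] = scores["total"].to_numpy()
        table["quintile"] = scores["quintile"].to_numpy()
        table.attrs["true_log_hr"] = log_hr
        cohorts.append(table)
    return cohorts


def _public_fields(config: SimulationConfig) -> dict:
    return {k: v for k, v in config.__dict__.items()
            if not k.startswith("_")}
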