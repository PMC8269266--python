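"""Synthetic community generator.

Emulates a latitudinal multi-site sediment survey: a regional species pool
with a phylogeny and phylogenetically conserved environmental optima, local
communities drawn under controllable assembly regimes (neutral immigration,
environmental selection, dispersal limitation, or mixtures), and a sample
design of locations x sites x depth layers with per-sample read depths drawn
from the survey's printed range (19,206-43,750 reads).

The neutral sampler follows Sloan's stationary distribution: a taxon's local
relative abundance is Beta(N*m*p_i, N*m*(1-p_i)) around its regional mean
p_i, and reads are a multinomial draw on the realised local abundances.
Selection multiplies the pool by a Gaussian filter exp(-(opt-env)^2/(2*s^2))
on the Brownian trait optima; dispersal limitation shrinks the immigration
rate with e-folding distance from the regional pool centroid.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .betadiv import haversine_km
from .errors import InvalidArgumentError

__all__ = [
    "Location",
    "StudyDesign",
    "RegimeSpec",
    "MetacommunityModel",
    "simulate_tree",
    "evolve_traits",
    "simulate_metacommunity",
    "sloan_sample",
    "simulate_dataset",
    "write_dataset",
    "default_design",
]

DEPTH_LAYERS = ("0-10", "10-20", "20-30")


@dataclass(frozen=True)
class Location:
    name: str
    latitude: float
    longitude: float


@dataclass
class StudyDesign:
    """Sampling design: locations along a gradient, sites, depth layers.

    ``env_gradient`` maps a covariate name to ``(intercept, slope_per_degree_
    latitude, noise_sd)``; covariates are generated per sample as a linear
    function of latitude plus Gaussian noise.
    """

    locations: list[Location]
    sites_per_location: int | dict[str, int] = 6
    depth_layers: tuple[str, ...] = DEPTH_LAYERS
    depth_range: tuple[int, int] = (19206, 43750)
    env_gradient: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    depth_env_offsets: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.depth_range[0] < 1:
            raise InvalidArgumentError("depth_range minimum must be >= 1")
        if self.depth_range[0] > self.depth_range[1]:
            raise InvalidArgumentError("depth_range must be (min, max) with min <= max")

    def sites_at(self, location: str) -> int:
        if isinstance(self.sites_per_location, dict):
            return self.sites_per_location[location]
        return self.sites_per_location

    @property
    def n_samples(self) -> int:
        return sum(
            self.sites_at(loc.name) * len(self.depth_layers) for loc in self.locations
        )


# Seven mangrove reserves along the Southeast China coast, north to south.
_DEFAULT_LOCATIONS = [
    Location("FT", 22.52, 114.03),
    Location("ZJK", 28.02, 120.58),
    Location("XMD", 24.45, 118.07),
    Location("YLW", 21.60, 109.76),
    Location("SK", 19.90, 110.58),
    Location("DZG", 19.95, 110.57),
    Location("ZJ", 21.20, 110.40),
]

_DEFAULT_GRADIENT = {
    "MAT": (38.0, -0.68, 0.4),       # deg C, cooler northwards
    "MAP": (3600.0, -75.0, 60.0),    # mm / yr
    "salinity": (34.0, -0.45, 0.8),  # ppt
    "pH": (6.2, 0.035, 0.12),
    "TOC": (28.0, -0.5, 1.5),        # g / kg
    "TN": (2.6, -0.04, 0.15),        # g / kg
}


def default_design(
    sites_per_location: int | dict[str, int] | None = None,
) -> StudyDesign:
    """The seven-location survey design; FT carries seven sites by default."""
    if sites_per_location is None:
        sites_per_location = {loc.name: 6 for loc in _DEFAULT_LOCATIONS}
        sites_per_location["FT"] = 7
    return StudyDesign(
        locations=list(_DEFAULT_LOCATIONS),
        sites_per_location=sites_per_location,
        env_gradient=dict(_DEFAULT_GRADIENT),
    )


@dataclass
class RegimeSpec:
    """Assembly regime: which processes act and how strongly.

    kind ``neutral`` uses immigration ``m`` only; ``selection`` additionally
    filters by ``selection_strength`` (trait units; smaller = stronger);
    ``dispersal_limited`` decays ``m`` with ``dispersal_scale`` (km);
    ``mixed`` convex-combines component regimes with ``mix_weights``.
    """

    kind: str = "neutral"
    m: float | None = None
    selection_strength: float | None = None
    dispersal_scale: float | None = None
    components: list["RegimeSpec"] | None = None
    mix_weights: list[float] | None = None

    def __post_init__(self) -> None:
        kinds = {"neutral", "selection", "dispersal_limited", "mixed"}
        if self.kind not in kinds:
            raise InvalidArgumentError(f"unknown regime kind {self.kind!r}")
        if self.kind == "mixed":
            if not self.components or not self.mix_weights:
                raise InvalidArgumentError("mixed regime needs components and weights")
            if len(self.components) != len(self.mix_weights):
                raise InvalidArgumentError("one weight per component regime")
            w = np.asarray(self.mix_weights, dtype=float)
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise InvalidArgumentError("mix_weights must be nonnegative, sum to 1")
            return
        if self.m is None or not (0 < self.m <= 1):
            raise InvalidArgumentError("immigration m must lie in (0, 1]")
        if self.kind == "selection" and (
            self.selection_strength is None or self.selection_strength <= 0
        ):
            raise InvalidArgumentError("selection regime needs selection_strength > 0")
        if self.kind == "dispersal_limited" and (
            self.dispersal_scale is None or self.dispersal_scale <= 0
        ):
            raise InvalidArgumentError("dispersal_limited regime needs dispersal_scale > 0")


@dataclass
class MetacommunityModel:
    """Regional species pool: abundances, phylogeny, and trait optima."""

    n_taxa: int
    source_abundances: np.ndarray
    tree: TreeNode
    trait_optima: pd.Series
    trait_sigma: float

    def __post_init__(self) -> None:
        p = np.asarray(self.source_abundances, dtype=float)
        if (p <= 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError(
                "source_abundances must be strictly positive and sum to 1"
            )
        tips = {t.name for t in self.tree.tips()}
        if set(self.trait_optima.index) != tips:
            raise InvalidArgumentError("trait_optima must cover exactly the tree tips")

    @classmethod
    def simulate(
        cls,
        n_taxa: int,
        seed: int,
        distribution: str = "lognormal",
        trait_sigma: float = 1.0,
        **dist_params,
    ) -> "MetacommunityModel":
        """Build a pool: Yule tree, Brownian optima, ranked abundances."""
        ss = np.random.SeedSequence(seed)
        s_tree, s_ab, s_tr, s_perm = (
            int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)
        )
        tree = simulate_tree(n_taxa, s_tree)
        abund = simulate_metacommunity(n_taxa, distribution, s_ab, **dist_params)
        # decouple abundance rank from tree position: tip labels follow tree
        # traversal order, so ranked abundances must be shuffled across taxa
        # or the pool itself would carry phylogenetic signal in abundance
        abund = np.random.default_rng(s_perm).permutation(abund)
        optima = evolve_traits(tree, trait_sigma, s_tr)
        return cls(n_taxa, abund, tree, optima, trait_sigma)

    @property
    def otu_ids(self) -> list[str]:
        return [f"OTU_{i + 1:04d}" for i in range(self.n_taxa)]


class _SimNode:
    __slots__ = ("children", "length", "name")

    def __init__(self) -> None:
        self.children: list[_SimNode] = []
        self.length = 0.0
        self.name: str | None = None


def _to_newick(node: _SimNode) -> str:
    if not node.children:
        return f"{node.name}:{node.length:.10g}"
    inner = ",".join(_to_newick(c) for c in node.children)
    return f"({inner}):{node.length:.10g}"


def simulate_tree(n_taxa: int, seed: int | None = None) -> TreeNode:
    """Pure-birth (Yule, rate 1) tree with ``n_taxa`` tips named OTU_0001...

    Forward simulation with exponential waiting times; all tips are
    contemporaneous so the tree is ultrametric, and every branch length is
    strictly positive.
    """
    if n_taxa < 2:
        raise InvalidArgumentError(f"need at least 2 taxa, got {n_taxa}")
    rng = np.random.default_rng(seed)
    root = _SimNode()
    active = [_SimNode(), _SimNode()]
    root.children = list(active)
    while len(active) < n_taxa:
        k = len(active)
        dt = rng.exponential(1.0 / k)
        for nd in active:
            nd.length += dt
        i = int(rng.integers(k))
        parent = active[i]
        kids = [_SimNode(), _SimNode()]
        parent.children = kids
        active[i] = kids[0]
        active.append(kids[1])
    dt = rng.exponential(1.0 / n_taxa)
    for nd in active:
        nd.length += dt
    # name tips in a deterministic traversal order
    counter = [0]

    def _name(node: _SimNode) -> None:
        if not node.children:
            counter[0] += 1
            node.name = f"OTU_{counter[0]:04d}"
        for c in node.children:
            _name(c)

    _name(root)
    newick = "(" + ",".join(_to_newick(c) for c in root.children) + ");"
    return TreeNode.read(_io.StringIO(newick), format="newick", convert_underscores=False)


def evolve_traits(tree: TreeNode, sigma: float, seed: int | None = None) -> pd.Series:
    """Brownian motion of a trait along the tree from a root value of 0.

    A tip's optimum has variance sigma^2 x root-to-tip path length; shared
    ancestry induces the phylogenetic covariance the null models exploit.
    """
    if sigma <= 0:
        raise InvalidArgumentError(f"sigma must be > 0, got {sigma}")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        bl = node.length or 0.0
        val = values[id(node.parent)] + rng.normal(0.0, sigma * np.sqrt(max(bl, 0.0)))
        values[id(node)] = val
        if node.is_tip():
            out[node.name] = val
    return pd.Series(out).sort_index()


def simulate_metacommunity(
    n_taxa: int,
    distribution: str = "lognormal",
    seed: int | None = None,
    mu: float = 0.0,
    sd: float = 1.0,
    alpha: float = 0.99,
) -> np.ndarray:
    """Regional relative abundances, ranked descending (ties by taxon order).

    ``lognormal(mu, sd)`` draws iid lognormal abundances; ``logseries(alpha)``
    draws iid log-series counts with shape parameter ``alpha`` in (0, 1),
    which produces the heavier singleton tail typical of Fisher's series.
    """
    if n_taxa < 1:
        raise InvalidArgumentError("n_taxa must be >= 1")
    rng = np.random.default_rng(seed)
    if distribution == "lognormal":
        if sd <= 0:
            raise InvalidArgumentError("lognormal sd must be > 0")
        raw = rng.lognormal(mu, sd, n_taxa)
    elif distribution == "logseries":
        if not (0 < alpha < 1):
            raise InvalidArgumentError("logseries alpha must be in (0, 1)")
        raw = rng.logseries(alpha, n_taxa).astype(float)
    else:
        raise InvalidArgumentError(f"unknown distribution {distribution!r}")
    raw = np.sort(raw)[::-1]
    return raw / raw.sum()


def _sloan_column(
    p: np.ndarray, m: float, depth: int, rng: np.random.Generator
) -> np.ndarray:
    a = depth * m * p
    b = depth * m * (1.0 - p)
    local = rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))
    tot = local.sum()
    if tot <= 0:  # pathological; fall back on the pool itself
        local = p.copy()
        tot = local.sum()
    return rng.multinomial(depth, local / tot)


def sloan_sample(
    source_abundances: np.ndarray,
    m: float,
    N: int,
    n_samples: int,
    seed: int | None = None,
    otu_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Draw local communities from the Sloan neutral stationary distribution.

    Every column sums to exactly ``N`` reads.
    """
    p = np.asarray(source_abundances, dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise InvalidArgumentError("source abundances must be a probability vector")
    if not (0 < m <= 1):
        raise InvalidArgumentError("m must lie in (0, 1]")
    if N < 1:
        raise InvalidArgumentError("N must be >= 1")
    rng = np.random.default_rng(seed)
    if len(p) == 1:
        data = np.full((1, n_samples), N, dtype=np.int64)
    else:
        data = np.column_stack(
            [_sloan_column(p, m, N, rng) for _ in range(n_samples)]
        )
    ids = otu_ids or [f"OTU_{i + 1:04d}" for i in range(len(p))]
    cols = [f"S{i + 1:03d}" for i in range(n_samples)]
    return pd.DataFrame(data, index=pd.Index(ids, name="otu_id"), columns=cols)


def _regime_pool_and_m(
    regime: RegimeSpec,
    pool: np.ndarray,
    optima: np.ndarray,
    env: float,
    dist_km: float,
) -> tuple[np.ndarray, float]:
    """Per-sample immigration source and rate under one regime."""
    if regime.kind == "mixed":
        pools, ms = [], []
        for comp, w in zip(regime.components, regime.mix_weights):
            cp, cm = _regime_pool_and_m(comp, pool, optima, env, dist_km)
            pools.append(w * cp)
            ms.append(w * cm)
        mixed = np.sum(pools, axis=0)
        return mixed / mixed.sum(), float(np.sum(ms))
    m = regime.m
    if regime.kind == "selection":
        w = np.exp(-((optima - env) ** 2) / (2.0 * regime.selection_strength**2))
        filt = pool * np.maximum(w, 1e-300)
        return filt / filt.sum(), m
    if regime.kind == "dispersal_limited":
        return pool, m * float(np.exp(-dist_km / regime.dispersal_scale))
    return pool, m


def simulate_dataset(
    design: StudyDesign,
    model: MetacommunityModel,
    regime: RegimeSpec,
    seed: int | None = None,
    env_mode: str = "latitude",
    env_values: np.ndarray | None = None,
    env_quantile: float = 0.5,
    block_quantiles: tuple[float, float] = (0.2, 0.8),
) -> tuple[pd.DataFrame, pd.DataFrame, TreeNode]:
    """Simulate the full survey: counts, sample metadata, and the tree.

    One column per (location, site, depth layer); read depth uniform on
    ``design.depth_range``. The selection environment is either tied to
    latitude and depth layer, mapped onto the trait scale (``latitude``),
    identical everywhere (``constant`` = median optimum), split into two
    latitudinal blocks at opposite trait quantiles (``two_block``), or
    supplied per sample via ``env_values``.
    """
    rng = np.random.default_rng(seed)
    otu_ids = model.otu_ids
    tips = [t.name for t in model.tree.tips()]
    if set(tips) != set(otu_ids):
        raise InvalidArgumentError("model tree tips must match model otu ids")
    optima = model.trait_optima.loc[otu_ids].to_numpy()
    pool = np.asarray(model.source_abundances, dtype=float)

    # sample book-keeping
    records = []
    for loc in design.locations:
        n_sites = design.sites_at(loc.name)
        for s in range(n_sites):
            lat = loc.latitude + 0.004 * s
            lon = loc.longitude + 0.006 * s
            for d, layer in enumerate(design.depth_layers):
                records.append((loc.name, s + 1, layer, d, lat, lon))
    n = len(records)
    lats = np.array([r[4] for r in records])
    lons = np.array([r[5] for r in records])

    # selection environment on the trait scale
    opt_sd = float(np.std(optima)) or 1.0
    opt_mean = float(np.mean(optima))
    if env_values is not None:
        env = np.asarray(env_values, dtype=float)
        if len(env) != n:
            raise InvalidArgumentError("env_values must have one entry per sample")
    elif env_mode == "constant":
        env = np.full(n, float(np.quantile(optima, env_quantile)))
    elif env_mode == "two_block":
        lo, hi = np.quantile(optima, list(block_quantiles))
        median_lat = float(np.median(lats))
        env = np.where(lats >= median_lat, hi, lo)
    elif env_mode == "latitude":
        offsets = design.depth_env_offsets or tuple(
            0.3 * i for i in range(len(design.depth_layers))
        )
        z = (lats - lats.mean()) / (lats.std() or 1.0)
        depth_idx = np.array([r[3] for r in records])
        env = (
            opt_mean
            + opt_sd * z
            + opt_sd * np.array([offsets[i] for i in depth_idx])
            + rng.normal(0.0, 0.1 * opt_sd, n)
        )
    else:
        raise InvalidArgumentError(f"unknown env_mode {env_mode!r}")

    # distance to the regional pool centroid (dispersal limitation)
    cen_lat, cen_lon = float(lats.mean()), float(lons.mean())
    dist_km = np.array(
        [haversine_km(lats[i], lons[i], cen_lat, cen_lon) for i in range(n)]
    )

    counts = np.empty((model.n_taxa, n), dtype=np.int64)
    depths = rng.integers(design.depth_range[0], design.depth_range[1] + 1, n)
    for i in range(n):
        p_i, m_i = _regime_pool_and_m(regime, pool, optima, env[i], dist_km[i])
        m_i = min(max(m_i, 1e-6), 1.0)
        counts[:, i] = _sloan_column(p_i, m_i, int(depths[i]), rng)

    sample_ids = [f"{r[0]}{r[1]}-{r[3] + 1}" for r in records]
    cdf = pd.DataFrame(
        counts, index=pd.Index(otu_ids, name="otu_id"), columns=sample_ids
    )
    meta = pd.DataFrame(
        {
            "location": [r[0] for r in records],
            "site": [r[1] for r in records],
            "depth_layer": [r[2] for r in records],
            "latitude": lats,
            "longitude": lons,
            "env": env,
            "regime": regime.kind,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for cov, (icpt, slope, noise_sd) in design.env_gradient.items():
        meta[cov] = icpt + slope * lats + rng.normal(0.0, noise_sd, n)
    return cdf, meta, model.tree


def write_dataset(
    prefix,
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    tree: TreeNode,
    params: dict | None = None,
) -> dict[str, str]:
    """Write counts TSV, metadata TSV, newick tree, and a JSON parameter sidecar."""
    from . import io as eio

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": f"{prefix}.counts.tsv",
        "metadata": f"{prefix}.metadata.tsv",
        "tree": f"{prefix}.tree.nwk",
        "params": f"{prefix}.params.json",
    }
    eio.write_count_table(counts, paths["counts"])
    eio.write_metadata(meta, paths["metadata"])
    eio.write_tree(tree, paths["tree"])
    Path(paths["params"]).write_text(json.dumps(params or {}, indent=2, sort_keys=True))
    return paths
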