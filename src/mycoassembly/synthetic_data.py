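"""Synthetic ASV tables with known ground truth.

The generator is the exact sampling dual of the Sloan neutral model:
per sample, a community composition is drawn from Dirichlet(N*m*p) over
the metacommunity vector p, and reads from Multinomial(N, composition).
The marginal per-taxon relative abundance is then Beta(N*m*p_i,
N*m*(1-p_i)), which is exactly the distribution the neutral fit assumes,
so fitting communities simulated here must recover m (the central
recovery property of the pipeline).

``simulate_study`` reproduces the geometry of a global survey design:
16 sites (real coastal coordinates spanning the Pacific and Atlantic),
12 individuals per site, three sample types (leaf, root, sediment),
site-specific metacommunities whose similarity decays as
exp(-distance/decay_scale), type-specific migration rates, and planted
host-selected and dispersal-limited taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln

from ._utils import as_rng
from .core_neutral import sloan_occupancy_curve
from .data_io import RANKS, UNCLASSIFIED, CountTable
from .distance_decay import haversine_km

# Survey sites: code, name, ocean, latitude, longitude.
SITE_TABLE = pd.DataFrame(
    [
        ("AK", "Alaska - North", "Pacific", 64.485428, -164.76189),
        ("AI", "Alaska - South", "Pacific", 55.328899, -162.82121),
        ("BB", "California - North", "Pacific", 38.319755, -123.05514),
        ("SD", "California - South", "Pacific", 32.713756, -117.22547),
        ("QU", "Canada", "Atlantic", 49.11237, -68.17593),
        ("CR", "Croatia", "Atlantic", 44.21155, 15.4906946),
        ("FR", "French Mediterranean", "Atlantic", 43.446971, 3.661503),
        ("JN", "Japan - North", "Pacific", 43.021167, 144.903217),
        ("JS", "Japan - South", "Pacific", 34.297834, 132.91631),
        ("MA", "Massachusetts", "Atlantic", 42.42014, -70.91544),
        ("NC", "North Carolina", "Atlantic", 34.692458, -76.622589),
        ("NN", "Norway", "Atlantic", 67.2667233, 15.2560633),
        ("PO", "Portugal", "Atlantic", 37.01427, -7.493273),
        ("SW", "Sweden", "Atlantic", 58.3131, 11.5488),
        ("UK", "Wales", "Atlantic", 52.990731, -4.450321),
        ("WA", "Washington", "Pacific", 46.474, -124.028),
    ],
    columns=["site_code", "site_name", "ocean", "latitude", "longitude"],
)

_FUNGAL_ORDERS = (
    "Capnodiales",
    "Pleosporales",
    "Agaricales",
    "Saccharomycetales",
    "Lobulomycetales",
    "Hypocreales",
    "Eurotiales",
    "Malasseziales",
    "Helotiales",
    "Chytridiales",
)


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of the synthetic survey; defaults mirror the global
    eelgrass design (16 sites x 12 individuals x 3 sample types = 576
    samples, ~5,000 reads per sample, migration rates of order 0.001)."""

    n_sites: int = 16
    n_individuals: int = 12
    sample_types: tuple[str, ...] = ("leaf", "root", "sediment")
    site_table: pd.DataFrame = field(default_factory=lambda: SITE_TABLE.copy())
    reads_per_sample: int = 5000
    n_taxa: int = 600
    lognormal_mu: float = -14.0
    lognormal_sigma: float = 3.0
    migration: dict = field(
        default_factory=lambda: {"leaf": 0.001, "root": 0.002, "sediment": 0.001}
    )
    decay_scale_km: float = 2000.0
    site_sigma: float = 1.0
    planted_selected: int = 5
    planted_dispersal_limited: int = 5
    n_host_taxa: int = 5
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_sites * self.n_individuals * len(self.sample_types)


def simulate_metacommunity(S: int, mu: float = -14.0, sigma: float = 3.0, seed=None):
    """Long-tailed (log-normal) metacommunity relative abundances,
    normalized to sum 1."""
    if S < 2:
        raise ValueError("need at least 2 taxa")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = as_rng(seed)
    p = rng.lognormal(mu, sigma, S)
    return p / p.sum()


def sloan_occupancy(p, N: float, m: float) -> np.ndarray:
    """Sloan prediction 1 - BetaCDF(1/N; N m p, N m (1-p))."""
    return sloan_occupancy_curve(p, N, m)


def exact_occupancy(p, N: float, m: float) -> np.ndarray:
    """Exact detection probability under the Dirichlet-multinomial dual:
    1 - P(count = 0) with count ~ BetaBinomial(N; N m p, N m (1-p))."""
    p = np.asarray(p, dtype=float)
    a = N * m * p
    b = N * m * (1.0 - p)
    return 1.0 - np.exp(betaln(a, b + N) - betaln(a, b))


def _dirichlet_rows(rng, alpha: np.ndarray, n: int) -> np.ndarray:
    """n Dirichlet(alpha) draws via gammas; tolerant of tiny shapes."""
    g = rng.gamma(np.broadcast_to(alpha, (n, alpha.size)))
    sums = g.sum(axis=1)
    dead = sums == 0
    if dead.any():  # vanishingly rare; put all mass on the largest alpha
        g[dead, np.argmax(alpha)] = 1.0
        sums = g.sum(axis=1)
    return g / sums[:, None]


def simulate_neutral_samples(
    p, n_samples: int, N: int, m: float, seed=None, sample_ids=None, asv_ids=None
) -> CountTable:
    """Neutral local communities: composition ~ Dirichlet(N*m*p), reads
    ~ Multinomial(N, composition).  Every row sums exactly to N."""
    p = np.asarray(p, dtype=float)
    if not 0 < m <= 1:
        raise ValueError("m must lie in (0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = as_rng(seed)
    comp = _dirichlet_rows(rng, N * m * p, n_samples)
    counts = rng.multinomial(int(N), comp)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    if asv_ids is None:
        asv_ids = [f"ASV{j:05d}" for j in range(p.size)]
    return CountTable(
        pd.DataFrame(counts.astype(np.int64), index=list(sample_ids), columns=list(asv_ids))
    )


def plant_structures(
    table: CountTable,
    meta: pd.DataFrame,
    n_selected: int,
    n_limited: int,
    seed=None,
    selected_fraction: float = 0.004,
    limited_fraction: float = 0.20,
) -> tuple[CountTable, pd.DataFrame]:
    """Insert exemplar non-neutral taxa into a neutral table.

    Selected taxa appear in *every* sample at a low fixed count
    (occupancy 1, low abundance -> should classify "above" the neutral
    band); dispersal-limited taxa appear at high count in the samples of
    exactly one site (high abundance, low occupancy -> "below").  Row
    sums are restored to their original totals by re-rarefaction.
    Returns the augmented table and a ground-truth frame.
    """
    rng = as_rng(seed)
    counts = table.counts.copy()
    totals = counts.sum(axis=1)
    n_total = int(totals.iloc[0])
    sel_count = max(1, round(selected_fraction * n_total))
    lim_count = max(1, round(limited_fraction * n_total))
    sites = meta.loc[table.sample_ids, "site_code"]
    site_codes = sites.unique()
    new_cols = {}
    truth_rows = [
        {"asv_id": a, "true_class": "neutral", "core_flag": False}
        for a in table.asv_ids
    ]
    for i in range(n_selected):
        name = f"SEL{i:03d}"
        new_cols[name] = np.full(len(counts), sel_count, dtype=np.int64)
        truth_rows.append(
            {"asv_id": name, "true_class": "selected", "core_flag": True}
        )
    for i in range(n_limited):
        name = f"LIM{i:03d}"
        home = site_codes[rng.integers(len(site_codes))]
        col = np.where(sites.to_numpy() == home, lim_count, 0).astype(np.int64)
        new_cols[name] = col
        truth_rows.append(
            {"asv_id": name, "true_class": "dispersal_limited", "core_flag": False}
        )
    if new_cols:
        counts = pd.concat([counts, pd.DataFrame(new_cols, index=counts.index)], axis=1)
    # restore original per-sample totals without replacement
    out = np.empty_like(counts.to_numpy())
    for i, sid in enumerate(counts.index):
        row = counts.iloc[i].to_numpy()
        out[i] = rng.multivariate_hypergeometric(row, int(totals.loc[sid]))
    planted = CountTable(pd.DataFrame(out, index=counts.index, columns=counts.columns))
    truth = pd.DataFrame(truth_rows).set_index("asv_id")
    return planted, truth


def _site_metacommunities(design: StudyDesign, rng) -> tuple[np.ndarray, np.ndarray]:
    """Global pool plus per-site perturbed metacommunities whose
    log-abundance fields are correlated exp(-d/decay_scale) across
    sites."""
    pool = simulate_metacommunity(
        design.n_taxa, design.lognormal_mu, design.lognormal_sigma, rng
    )
    sites = design.site_table.iloc[: design.n_sites]
    lat = sites["latitude"].to_numpy()
    lon = sites["longitude"].to_numpy()
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    corr = np.exp(-np.asarray(d) / design.decay_scale_km)
    corr += 1e-9 * np.eye(len(sites))
    chol = np.linalg.cholesky(corr)
    z = chol @ rng.standard_normal((len(sites), design.n_taxa))
    logp = np.log(pool)[None, :] + design.site_sigma * z
    site_p = np.exp(logp)
    site_p /= site_p.sum(axis=1, keepdims=True)
    return pool, site_p


def simulate_study(design: StudyDesign | None = None):
    """Generate a full synthetic survey.

    Returns (CountTable, metadata, taxonomy, ground truth).  Metadata
    carries real site coordinates so geographic scales are realistic;
    reproducible bit-for-bit under the design seed.
    """
    if design is None:
        design = StudyDesign()
    if design.n_sites > len(design.site_table):
        raise ValueError("not enough site coordinates for n_sites")
    rng = as_rng(design.seed)
    pool, site_p = _site_metacommunities(design, rng)
    sites = design.site_table.iloc[: design.n_sites]
    blocks, meta_rows = [], []
    for si, site in sites.reset_index(drop=True).iterrows():
        for stype in design.sample_types:
            m = design.migration[stype]
            ids = [
                f"{site.site_code}_{stype}_{i + 1:02d}"
                for i in range(design.n_individuals)
            ]
            block = simulate_neutral_samples(
                site_p[si],
                design.n_individuals,
                design.reads_per_sample,
                m,
                seed=rng,
                sample_ids=ids,
            )
            blocks.append(block.counts)
            for i, sid in enumerate(ids):
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "site_code": site.site_code,
                        "site_name": site.site_name,
                        "ocean": site.ocean,
                        "sample_type": stype,
                        "latitude": site.latitude,
                        "longitude": site.longitude,
                        "individual": i + 1,
                    }
                )
    table = CountTable(pd.concat(blocks, axis=0))
    meta = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    table, truth = plant_structures(
        table, meta, design.planted_selected, design.planted_dispersal_limited, rng
    )
    truth["meta_abundance"] = pd.Series(pool, index=table.asv_ids[: design.n_taxa])
    # host (nonfungal) taxa: modest read counts on every leaf sample;
    # removed downstream by the domain-level taxonomy filter
    counts = table.counts.copy()
    is_leaf = meta.loc[table.sample_ids, "sample_type"].to_numpy() == "leaf"
    host_ids = []
    for i in range(design.n_host_taxa):
        name = f"HOST{i:03d}"
        host_ids.append(name)
        counts[name] = np.where(
            is_leaf, rng.poisson(0.02 * design.reads_per_sample, len(counts)), 0
        ).astype(np.int64)
        truth.loc[name] = {
            "true_class": "nonfungal",
            "core_flag": False,
            "meta_abundance": np.nan,
        }
    table = CountTable(counts)
    tax = _synthetic_taxonomy(table.asv_ids, host_ids, rng)
    return table, meta, tax, truth.loc[table.asv_ids]


def _synthetic_taxonomy(asv_ids, host_ids, rng) -> pd.DataFrame:
    host = set(host_ids)
    rows = []
    for asv in asv_ids:
        if asv in host:
            rows.append(
                ["Viridiplantae"] + [UNCLASSIFIED] * (len(RANKS) - 1)
            )
        else:
            order = _FUNGAL_ORDERS[rng.integers(len(_FUNGAL_ORDERS))]
            rows.append(
                ["Fungi", UNCLASSIFIED, UNCLASSIFIED, order]
                + [UNCLASSIFIED] * (len(RANKS) - 4)
            )
    return pd.DataFrame(rows, columns=list(RANKS), index=pd.Index(asv_ids, name="asv_id"))


def simulate_core_community(
    n_drivers: int = 10,
    n_background: int = 200,
    n_sites: int = 6,
    samples_per_site: int = 10,
    N: int = 2000,
    m_background: float = 0.01,
    driver_share: float = 0.8,
    seed=None,
):
    """Structured community with known core drivers.

    ``n_drivers`` near-ubiquitous taxa carry most of the reads over a
    sparse neutral background of rare taxa; the drivers are the ground
    truth core.  Driver j is absent from j-1 random samples (so the
    occupancy ranking orders drivers deterministically) and its
    per-sample abundance noise grows with j, so each successive driver
    adds a substantial share of the community's Bray-Curtis turnover
    while each rare background taxon adds only a sliver.

    Returns (CountTable, metadata, driver id list).
    """
    rng = as_rng(seed)
    n_samples = n_sites * samples_per_site
    if 2 * n_drivers >= n_samples:
        raise ValueError("need more samples than drivers")
    sigmas = np.linspace(0.3, 2.0, n_drivers)
    w = driver_share * 1.2 ** np.arange(n_drivers)
    w *= driver_share / w.sum()
    p_bg = np.full(n_background, 1.0 / n_background)
    absent = {
        j: rng.choice(n_samples, size=2 * j, replace=False) for j in range(n_drivers)
    }
    counts = np.empty((n_samples, n_drivers + n_background), dtype=np.int64)
    for s in range(n_samples):
        noise = rng.lognormal(-(sigmas**2) / 2, sigmas)
        dq = w * noise
        for j in range(n_drivers):
            if s in absent[j]:
                dq[j] = 0.0
        dq *= driver_share / dq.sum()
        bg = _dirichlet_rows(rng, N * m_background * p_bg, 1)[0]
        comp = np.concatenate([dq, (1.0 - driver_share) * bg])
        counts[s] = rng.multinomial(N, comp / comp.sum())
        # drivers meant to be present must not drop out by sampling
        for j in range(n_drivers):
            if s not in absent[j] and counts[s, j] == 0:
                donor = int(np.argmax(counts[s]))
                counts[s, donor] -= 1
                counts[s, j] = 1
    driver_ids = [f"DRV{i:03d}" for i in range(n_drivers)]
    bg_ids = [f"BG{i:04d}" for i in range(n_background)]
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    table = CountTable(
        pd.DataFrame(counts, index=sample_ids, columns=driver_ids + bg_ids)
    )
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "site_code": np.repeat(
                [f"SITE{i:02d}" for i in range(n_sites)], samples_per_site
            ),
        }
    ).set_index("sample_id", drop=False)
    return table, meta, driver_ids
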