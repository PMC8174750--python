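"""Abundance-occupancy analysis, ranked-contribution core identification,
Sloan neutral-model fitting, and deviation classification.

The Sloan model predicts, for a taxon at metacommunity relative
abundance p, the fraction of local communities in which it is detected:

    occupancy(p) = 1 - BetaCDF(d; N*m*p, N*m*(1 - p))

where N is the reference read depth per sample, d = 1/N the detection
limit, and m the migration rate (probability that a local death is
replaced by an immigrant rather than local reproduction).  m is the
single free parameter and is estimated by bounded least squares of
observed against predicted occupancy.  Taxa whose observed occupancy
exceeds the 95% Wilson band around the prediction are candidates for
host/environmental selection ("above"); taxa below the band are
candidates for selection-against or dispersal limitation ("below").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .data_io import CountTable

M_BOUNDS = (1e-6, 1.0)


@dataclass(frozen=True)
class AbundanceOccupancy:
    """Per-ASV mean relative abundance, occupancy and site consistency,
    computed on a table rarefied to a common depth."""

    frame: pd.DataFrame  # index asv_id; mean_rel_abund, occupancy, site_consistency
    n_samples: int
    n_sites: int
    depth: int  # common per-sample read depth of the underlying table

    @property
    def asv_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)


def abundance_occupancy(table: CountTable, meta: pd.DataFrame) -> AbundanceOccupancy:
    """Build the abundance-occupancy distribution of a (single sample
    type) table.

    The table must be rarefied to a common depth (equal row sums);
    all-zero ASVs are excluded.  Site consistency is the fraction of
    sites with at least one detection.
    """
    sums = table.sample_sums()
    if len(sums) == 0:
        raise ValueError("empty table")
    if sums.nunique() != 1:
        raise ValueError(
            "unequal per-sample totals; rarefy the table to a common depth first"
        )
    depth = int(sums.iloc[0])
    if depth == 0:
        raise ValueError("table has zero reads")
    counts = table.matrix()
    present = counts.sum(axis=0) > 0
    counts = counts[:, present]
    asv_ids = np.asarray(table.asv_ids)[present]
    rel = counts / depth
    n = counts.shape[0]
    sem = rel.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(counts.shape[1])
    occupancy = (counts > 0).mean(axis=0)
    sites = meta.loc[table.sample_ids, "site_code"].to_numpy()
    site_codes = np.unique(sites)
    detect = np.zeros((len(site_codes), counts.shape[1]), dtype=bool)
    for i, sc in enumerate(site_codes):
        detect[i] = (counts[sites == sc] > 0).any(axis=0)
    frame = pd.DataFrame(
        {
            "mean_rel_abund": rel.mean(axis=0),
            "sem_rel_abund": sem,
            "occupancy": occupancy,
            "site_consistency": detect.mean(axis=0),
        },
        index=pd.Index(asv_ids, name="asv_id"),
    )
    return AbundanceOccupancy(frame, len(sums), len(site_codes), depth)


def rank_asvs(
    ao: AbundanceOccupancy, w_occupancy: float = 0.5, w_sites: float = 0.5
) -> list[str]:
    """Rank ASVs by a composite occupancy index.

    Score = w_occupancy * (occupancy / max occupancy) + w_sites *
    (site consistency / max site consistency), descending; ties broken
    by descending mean relative abundance, then lexical ASV id.
    """
    if len(ao) == 0:
        raise ValueError("empty abundance-occupancy table")
    f = ao.frame
    score = (
        w_occupancy * f["occupancy"] / f["occupancy"].max()
        + w_sites * f["site_consistency"] / f["site_consistency"].max()
    )
    order = pd.DataFrame(
        {
            "score": score.to_numpy(),
            "p": f["mean_rel_abund"].to_numpy(),
            "asv_id": f.index.to_numpy(),
        }
    ).sort_values(
        by=["score", "p", "asv_id"], ascending=[False, False, True], kind="mergesort"
    )
    return order["asv_id"].tolist()


@dataclass(frozen=True)
class CoreResult:
    """Ranked contribution of ASVs to beta diversity and the resulting
    core set (a prefix of the ranking)."""

    ranking: list[str]
    contribution_curve: np.ndarray  # ratio of subset to full mean Bray-Curtis
    percent_increase: np.ndarray  # NaN at rank 1
    core_set: list[str]
    threshold: float

    def as_frame(self) -> pd.DataFrame:
        k = len(self.ranking)
        return pd.DataFrame(
            {
                "rank": np.arange(1, k + 1),
                "asv_id": self.ranking,
                "contribution": self.contribution_curve,
                "percent_increase": self.percent_increase,
                "in_core": [a in set(self.core_set) for a in self.ranking],
            }
        )


def _mean_bray_curtis_prefix(counts: np.ndarray, denominator: str) -> np.ndarray:
    """Mean pairwise Bray-Curtis of every ranked prefix, incrementally.

    ``counts`` columns must already be in ranking order.  With
    ``denominator="full"`` each pair's denominator is the full-table
    read total (so the curve is additive and monotone, the convention
    of ranked-contribution core analysis); with ``"subset"`` the
    literal Bray-Curtis of the prefix subtable is used.  Pairs with a
    zero denominator contribute 0.
    """
    n, k = counts.shape
    iu, ju = np.triu_indices(n, 1)
    num = np.zeros(len(iu))
    den = np.zeros(len(iu))
    totals = counts.sum(axis=1).astype(float)
    full_den = totals[iu] + totals[ju]
    out = np.empty(k)
    for j in range(k):
        col = counts[:, j].astype(float)
        num += np.abs(col[iu] - col[ju])
        den += col[iu] + col[ju]
        d = full_den if denominator == "full" else den
        with np.errstate(invalid="ignore", divide="ignore"):
            bc = np.where(d > 0, num / d, 0.0)
        out[j] = bc.mean()
    return out


def core_by_contribution(
    table: CountTable,
    ranking: list[str],
    threshold: float = 0.10,
    denominator: str = "full",
) -> CoreResult:
    """Identify the core as the ranked prefix whose members each add at
    least ``threshold`` (default 10%) to the explained beta diversity.

    contribution(k) = mean pairwise Bray-Curtis over the top-k ranked
    ASVs divided by the full-table mean; percent_increase(k) is the
    relative gain over rank k-1; the core runs through the last rank
    whose percent increase meets the threshold (rank 1 always
    included).  By default each pair's Bray-Curtis denominator is the
    full-table read total, which makes the contribution curve additive
    and monotone from near 0 to 1; ``denominator="subset"`` computes
    the literal Bray-Curtis of each prefix subtable instead.
    """
    if denominator not in ("full", "subset"):
        raise ValueError("denominator must be 'full' or 'subset'")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    missing = set(table.asv_ids) - set(ranking)
    if missing:
        raise ValueError(f"ranking does not cover ASVs: {sorted(missing)[:10]}")
    ranking = [a for a in ranking if a in set(table.asv_ids)]
    counts = table.counts[ranking].to_numpy()
    if counts[:, 0].sum() == 0:
        raise ValueError("rank-1 subtable has no reads")
    prefix_bc = _mean_bray_curtis_prefix(counts, denominator)
    full_bc = prefix_bc[-1]
    if full_bc == 0:
        raise ValueError("full table has zero mean Bray-Curtis")
    contribution = prefix_bc / full_bc
    pct = np.full(len(ranking), np.nan)
    prev = contribution[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct[1:] = 100.0 * (contribution[1:] - prev) / prev
    qualifying = np.where(pct[1:] >= 100.0 * threshold)[0]
    k_star = int(qualifying[-1]) + 2 if len(qualifying) else 1
    return CoreResult(
        ranking=ranking,
        contribution_curve=contribution,
        percent_increase=pct,
        core_set=ranking[:k_star],
        threshold=threshold,
    )


@dataclass(frozen=True)
class NeutralFit:
    """Fitted Sloan neutral model: migration rate, reference depth,
    detection limit, per-ASV predictions with 95% Wilson bands, and
    goodness of fit."""

    m: float
    N: float
    d: float
    r_squared: float
    frame: pd.DataFrame  # index asv_id; mean_rel_abund, occupancy, predicted, lower, upper
    n_samples: int


def sloan_occupancy_curve(p: np.ndarray, N: float, m: float) -> np.ndarray:
    """Predicted occupancy 1 - BetaCDF(1/N; N m p, N m (1-p))."""
    p = np.asarray(p, dtype=float)
    nm = N * m
    return 1.0 - stats.beta.cdf(1.0 / N, nm * p, nm * (1.0 - p))


def fit_sloan(
    ao: AbundanceOccupancy, N: float | None = None, abundance_error: bool = True
) -> NeutralFit:
    """Fit the Sloan neutral model to an abundance-occupancy
    distribution by bounded scalar least squares over m.

    N defaults to the (common) read depth of the table behind ``ao``;
    the detection limit is 1/N.  The 95% band around each predicted
    occupancy starts from the Wilson score interval with n = number of
    samples; because the prediction is evaluated at the *estimated*
    mean relative abundance, that estimate's standard error is
    propagated through the prediction curve and combined with the
    Wilson half-width in quadrature (the two error sources are
    independent).  Set ``abundance_error=False`` for the plain Wilson
    band.  R^2 is computed about the mean observed occupancy and may be
    negative for strongly non-neutral data.
    """
    if len(ao) < 10:
        raise ValueError("fewer than 10 ASVs; the fit is unidentifiable")
    if N is None:
        N = float(ao.depth)
    if N <= 0:
        raise ValueError("N must be positive")
    f = ao.frame
    p = f["mean_rel_abund"].to_numpy()
    occ = f["occupancy"].to_numpy()
    if np.allclose(occ, 1.0):
        raise ValueError("all taxa fully occupied; the fit is degenerate")

    def sse(m: float) -> float:
        return float(((occ - sloan_occupancy_curve(p, N, m)) ** 2).sum())

    res = optimize.minimize_scalar(
        sse, bounds=M_BOUNDS, method="bounded", options={"xatol": 1e-9}
    )
    m_hat = float(res.x)
    predicted = sloan_occupancy_curve(p, N, m_hat)
    lower, upper = proportion_confint(
        predicted * ao.n_samples, ao.n_samples, alpha=0.05, method="wilson"
    )
    if abundance_error and "sem_rel_abund" in f.columns:
        sem = f["sem_rel_abund"].to_numpy()
        p_lo = np.clip(p - 1.96 * sem, 1e-12, 1.0)
        p_hi = np.clip(p + 1.96 * sem, 1e-12, 1.0 - 1e-12)
        d_lo = np.abs(predicted - sloan_occupancy_curve(p_lo, N, m_hat))
        d_hi = np.abs(sloan_occupancy_curve(p_hi, N, m_hat) - predicted)
        lower = np.clip(
            predicted - np.sqrt((predicted - lower) ** 2 + d_lo**2), 0.0, 1.0
        )
        upper = np.clip(
            predicted + np.sqrt((upper - predicted) ** 2 + d_hi**2), 0.0, 1.0
        )
    ss_res = ((occ - predicted) ** 2).sum()
    ss_tot = ((occ - occ.mean()) ** 2).sum()
    r2 = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else np.nan
    frame = f.assign(predicted=predicted, lower=lower, upper=upper)
    return NeutralFit(m_hat, float(N), 1.0 / N, r2, frame, ao.n_samples)


def classify_deviation(ao: AbundanceOccupancy, fit: NeutralFit) -> pd.Series:
    """Label each ASV above / neutral / below the 95% band around the
    neutral prediction.  Deviation requires strict exceedance; boundary
    equality is neutral."""
    if list(ao.frame.index) != list(fit.frame.index):
        raise ValueError("fit was not computed on this abundance-occupancy table")
    occ = fit.frame["occupancy"]
    labels = pd.Series("neutral", index=fit.frame.index, name="deviation")
    labels[occ > fit.frame["upper"]] = "above"
    labels[occ < fit.frame["lower"]] = "below"
    return labels


def summarize_core(
    cores: dict[str, CoreResult],
    labels: dict[str, pd.Series],
    da: pd.DataFrame,
    tax: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Join core membership, neutral-model deviation and differential
    abundance into one summary row per ASV.

    Includes every ASV that belongs to at least one core and is
    significant in at least one differential-abundance comparison at
    adjusted p < alpha.  Deviation labels are listed in core order;
    comparison directions come from the sign of the log2 fold change.
    """
    sig = da[da["padj"] < alpha]
    rows = []
    core_asvs: dict[str, list[str]] = {t: list(c.core_set) for t, c in cores.items()}
    all_core = set().union(*core_asvs.values()) if core_asvs else set()
    for asv in sorted(all_core):
        hits = sig[sig["asv_id"] == asv]
        if hits.empty:
            continue
        member_types = [t for t, s in core_asvs.items() if asv in s]
        devs = []
        for t in member_types:
            lab = labels.get(t)
            devs.append(
                str(lab.loc[asv]) if lab is not None and asv in lab.index else "none"
            )
        comparisons = []
        for _, row in hits.iterrows():
            a, b = row["comparison"].split("_vs_")
            if row["log2fc"] >= 0:
                comparisons.append(f"{a} > {b}")
            else:
                comparisons.append(f"{b} > {a}")
        taxon = ""
        if tax is not None and asv in tax.index:
            named = [r for r in tax.loc[asv] if str(r) != "unclassified"]
            taxon = named[-1] if named else "unclassified"
        rows.append(
            {
                "asv_id": asv,
                "core_prediction": ", ".join(t.capitalize() for t in member_types),
                "neutral_deviation": ", ".join(
                    d.capitalize() if i == 0 else d for i, d in enumerate(devs)
                )
                if devs
                else "None",
                "significant_comparisons": "; ".join(comparisons),
                "taxonomy": taxon,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "asv_id",
            "core_prediction",
            "neutral_deviation",
            "significant_comparisons",
            "taxonomy",
        ],
    )
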