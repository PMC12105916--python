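"""SNP filtering and per-group genetic metrics.

The filters mirror standard reduced-representation QC: drop low-reproducibility
loci, keep one locus per sequencing tag, drop high-missingness loci and
samples, and drop fixed (monomorphic) loci.  Downstream metrics are the ones
the composite genetic value consumes: minor-allele-frequency classes, total
and private allele counts per group, observed heterozygosity over common
loci, and mean Euclidean genotype distances within and between groups.

An "allele" here is one of the (up to) two states of a biallelic locus; it is
present in a group when at least one copy is observed among the group's
non-missing calls.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .io_formats import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport", "MafClassification", "filter_genotypes", "classify_maf",
    "allele_accounting", "observed_heterozygosity", "genetic_distances",
    "pairwise_distances", "unit_metrics",
]


@dataclass
class FilterReport:
    """Loci/samples removed at each filtering step, in application order."""

    low_reproducibility: int
    tag_duplicates: int
    high_missing_loci: int
    fixed_loci: int
    high_missing_samples: int
    refixed_loci: int

    def as_dict(self) -> dict[str, int]:
        return self.__dict__.copy()


@dataclass
class MafClassification:
    """Per-locus minor-allele frequency and common/rare class.

    ``common`` is MAF above the common threshold (default 5%), ``rare`` is
    MAF between the rare floor (1%) and the common threshold inclusive,
    anything below the floor is ``neither``.
    """

    table: pd.DataFrame  # index locus_id; columns maf, maf_class

    def loci_in_class(self, maf_class: str) -> list[str]:
        return self.table.index[self.table["maf_class"] == maf_class].tolist()


# ---------------------------------------------------------------------------

def filter_genotypes(raw: GenotypeMatrix, cfg: RunConfig | None = None
                     ) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the locus/sample QC filters in a fixed, auditable order.

    Order: reproducibility → one per tag (keep least-missing locus, ties to
    the lexically lowest locus_id) → locus missingness → fixed loci →
    sample missingness → re-drop loci fixed by sample removal.
    """
    cfg = cfg or RunConfig()
    gm = raw
    v = gm.values

    # 1. reproducibility
    rep = gm.locus_meta["reproducibility"].to_numpy(float)
    keep = rep >= cfg.reproducibility_min
    n_rep = int((~keep).sum())
    gm = gm.subset(locus_idx=np.flatnonzero(keep))

    # 2. one locus per tag: least missingness, tie → lowest locus_id
    miss_frac = np.isnan(gm.values).mean(axis=0)
    order = sorted(
        range(gm.n_loci),
        key=lambda j: (gm.locus_meta["tag_id"].iloc[j], miss_frac[j], gm.locus_ids[j]),
    )
    keep_idx, seen_tags = [], set()
    for j in order:
        tag = gm.locus_meta["tag_id"].iloc[j]
        if tag not in seen_tags:
            seen_tags.add(tag)
            keep_idx.append(j)
    keep_idx.sort()
    n_tag = gm.n_loci - len(keep_idx)
    gm = gm.subset(locus_idx=keep_idx)

    # 3. locus missingness
    miss_frac = np.isnan(gm.values).mean(axis=0)
    keep = miss_frac <= cfg.locus_missing_max
    n_lmiss = int((~keep).sum())
    gm = gm.subset(locus_idx=np.flatnonzero(keep))

    # 4. fixed loci
    keep = ~_fixed_mask(gm.values)
    n_fixed = int((~keep).sum())
    gm = gm.subset(locus_idx=np.flatnonzero(keep))

    # 5. sample missingness
    smiss = np.isnan(gm.values).mean(axis=1) if gm.n_loci else np.zeros(gm.n_samples)
    keep_s = smiss <= cfg.sample_missing_max
    n_smiss = int((~keep_s).sum())
    gm = gm.subset(sample_idx=np.flatnonzero(keep_s))

    # 6. re-drop loci made fixed by sample removal
    keep = ~_fixed_mask(gm.values)
    n_refix = int((~keep).sum())
    gm = gm.subset(locus_idx=np.flatnonzero(keep))

    if gm.n_loci == 0:
        raise ValueError("no loci survive filtering")
    report = FilterReport(n_rep, n_tag, n_lmiss, n_fixed, n_smiss, n_refix)
    logger.info("genotype filtering (%s): %s", gm.species_id, report.as_dict())
    return gm, report


def _fixed_mask(values: np.ndarray) -> np.ndarray:
    """Loci with no variation among non-missing calls (incl. all-missing)."""
    if values.size == 0:
        return np.zeros(values.shape[1], dtype=bool)
    with np.errstate(invalid="ignore"):
        mn = np.nanmin(values, axis=0) if values.shape[0] else np.full(values.shape[1], np.nan)
        mx = np.nanmax(values, axis=0) if values.shape[0] else np.full(values.shape[1], np.nan)
    all_missing = np.isnan(values).all(axis=0)
    return all_missing | (mn == mx)


def classify_maf(gm: GenotypeMatrix, cfg: RunConfig | None = None) -> MafClassification:
    """Minor-allele frequency per locus over all non-missing calls."""
    cfg = cfg or RunConfig()
    n_called = (~np.isnan(gm.values)).sum(axis=0)
    if (n_called == 0).any():
        bad = [gm.locus_ids[j] for j in np.flatnonzero(n_called == 0)]
        raise ValueError(f"loci with zero non-missing calls: {bad[:10]}")
    p = np.nansum(gm.values, axis=0) / (2.0 * n_called)
    maf = np.minimum(p, 1.0 - p)
    cls = np.where(maf > cfg.maf_common, "common",
                   np.where(maf >= cfg.maf_rare_low, "rare", "neither"))
    return MafClassification(pd.DataFrame(
        {"maf": maf, "maf_class": cls}, index=pd.Index(gm.locus_ids, name="locus_id")
    ))


# ---------------------------------------------------------------------------

def _presence(values: np.ndarray) -> np.ndarray:
    """(n_loci, 2) booleans: [ref present, alt present] over the given rows."""
    ref = np.nansum((values == 0) | (values == 1), axis=0) > 0
    alt = np.nansum((values == 1) | (values == 2), axis=0) > 0
    return np.stack([ref, alt], axis=1)


def allele_accounting(gm: GenotypeMatrix, maf: MafClassification,
                      groups: dict[str, str], maf_class: str = "common") -> pd.DataFrame:
    """Total and private allele counts per group for one MAF class.

    ``groups`` maps sample_id → group label.  Counts are normalized by the
    species-wide number of alleles present in the class (over all samples of
    the matrix), per-class, so normalized values lie in [0, 1].
    """
    loci = maf.loci_in_class(maf_class)
    locus_idx = [gm.locus_ids.index(l) for l in loci]
    sample_pos = {s: i for i, s in enumerate(gm.sample_ids)}

    names = sorted(set(groups.values()))
    members = {g: [s for s, gg in groups.items() if gg == g] for g in names}
    for g, mem in members.items():
        mem_in = [m for m in mem if m in sample_pos]
        if not mem_in:
            raise ValueError(f"group {g!r} has no genotyped members")
        members[g] = mem_in

    vals = gm.values[:, locus_idx]
    species_present = _presence(vals)
    species_total = int(species_present.sum())

    pres = {g: _presence(vals[[sample_pos[s] for s in members[g]]]) for g in names}
    rows = []
    for g in names:
        others = np.zeros_like(species_present) if len(names) == 1 else np.any(
            [pres[h] for h in names if h != g], axis=0)
        total = int(pres[g].sum())
        private = int((pres[g] & ~others).sum())
        rows.append({
            "group": g,
            "maf_class": maf_class,
            "n_members": len(members[g]),
            "total_alleles": total,
            "private_alleles": private,
            "total_prop": total / species_total if species_total else np.nan,
            "private_prop": private / species_total if species_total else np.nan,
        })
    return pd.DataFrame(rows).set_index("group")


def observed_heterozygosity(gm: GenotypeMatrix, maf: MafClassification,
                            per: str = "individual",
                            groups: dict[str, str] | None = None) -> pd.Series:
    """Fraction of heterozygous calls over common-class loci.

    Per individual: (# genotype == 1) / (# non-missing common loci); NaN when
    an individual has no non-missing common locus.  Per group: mean over
    member values (NaN members excluded).
    """
    loci = maf.loci_in_class("common")
    idx = [gm.locus_ids.index(l) for l in loci]
    vals = gm.values[:, idx]
    n_called = (~np.isnan(vals)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_called > 0, (vals == 1).sum(axis=1) / n_called, np.nan)
    ind = pd.Series(ho, index=pd.Index(gm.sample_ids, name="sample_id"), name="ho")
    if (n_called == 0).any():
        logger.warning("%d individuals have no non-missing common loci",
                       int((n_called == 0).sum()))
    if per == "individual":
        return ind
    if per != "group":
        raise ValueError("per must be 'individual' or 'group'")
    if groups is None:
        raise ValueError("group-level heterozygosity requires a group map")
    out = {}
    for g in sorted(set(groups.values())):
        mem = [s for s, gg in groups.items() if gg == g and s in ind.index]
        out[g] = float(np.nanmean(ind[mem])) if mem else np.nan
    return pd.Series(out, name="ho").rename_axis("group")


# ---------------------------------------------------------------------------

def pairwise_distances(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise Euclidean distance on genotype vectors with missing data.

    Distances use only loci where both calls are non-missing and are rescaled
    by sqrt(L_total / L_shared) so pairs of different completeness stay
    comparable.  Pairs sharing no locus get NaN.
    """
    v = gm.values
    mask = ~np.isnan(v)
    filled = np.where(mask, v, 0.0)
    sq = filled**2
    # sum over shared loci of (a-b)^2, computed with masked cross terms
    g2 = sq @ mask.T + mask @ sq.T - 2.0 * (filled @ filled.T)
    g2 = np.maximum(g2, 0.0)
    shared = (mask.astype(float) @ mask.T.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(g2 * (gm.n_loci / shared))
    d[shared == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


def genetic_distances(gm: GenotypeMatrix, groups: dict[str, str],
                      between_mode: str = "mean_of_means") -> pd.DataFrame:
    """Mean within- and between-group Euclidean genotype distances.

    ``mean_within`` averages all pairs inside a group (NaN, flagged, for
    groups of one).  ``mean_between`` is, per group, the unweighted mean over
    other groups of the mean inter-individual distance (``mean_of_means``),
    or the mean over all inter-group pairs pooled (``pooled``).
    """
    if not groups:
        raise ValueError("need at least one group")
    d = pairwise_distances(gm)
    pos = {s: i for i, s in enumerate(gm.sample_ids)}
    names = sorted(set(groups.values()))
    members = {g: [pos[s] for s, gg in groups.items() if gg == g and s in pos]
               for g in names}
    for g, mem in members.items():
        if not mem:
            raise ValueError(f"group {g!r} has no genotyped members")

    if np.isnan(d[~np.eye(len(d), dtype=bool)]).any():
        logger.warning("some sample pairs share no non-missing loci; "
                       "those pairs are excluded from distance means")

    def block_mean(a: list[int], b: list[int]) -> float:
        sub = d[np.ix_(a, b)]
        return float(np.nanmean(sub)) if np.isfinite(sub).any() else np.nan

    rows = []
    for g in names:
        mem = members[g]
        if len(mem) >= 2:
            sub = d[np.ix_(mem, mem)]
            vals = sub[np.triu_indices(len(mem), k=1)]
            within = float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
        else:
            within = np.nan
        others = [h for h in names if h != g]
        if not others:
            between = np.nan
        elif between_mode == "mean_of_means":
            per = [block_mean(mem, members[h]) for h in others]
            per = [p for p in per if np.isfinite(p)]
            between = float(np.mean(per)) if per else np.nan
        elif between_mode == "pooled":
            all_vals = list(itertools.chain.from_iterable(
                d[np.ix_(mem, members[h])].ravel() for h in others))
            arr = np.asarray(all_vals)
            between = float(np.nanmean(arr)) if np.isfinite(arr).any() else np.nan
        else:
            raise ValueError("between_mode must be 'mean_of_means' or 'pooled'")
        rows.append({
            "group": g,
            "mean_within": within,
            "within_defined": np.isfinite(within),
            "mean_between": between,
            "between_defined": np.isfinite(between),
        })
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------

def unit_metrics(gm: GenotypeMatrix, groups: dict[str, str],
                 cfg: RunConfig | None = None) -> pd.DataFrame:
    """Per-group metric table feeding the composite genetic value.

    Columns: allele_prop (normalized total common alleles), heterozygosity
    (group mean Ho over common loci), dist_between, dist_within, n_members.
    """
    cfg = cfg or RunConfig()
    maf = classify_maf(gm, cfg)
    acc = allele_accounting(gm, maf, groups, maf_class="common")
    ho = observed_heterozygosity(gm, maf, per="group", groups=groups)
    dist = genetic_distances(gm, groups, between_mode=cfg.between_mode)
    out = pd.DataFrame({
        "allele_prop": acc["total_prop"],
        "heterozygosity": ho,
        "dist_between": dist["mean_between"],
        "dist_within": dist["mean_within"],
        "n_members": acc["n_members"].astype(float),
    })
    out.index.name = "unit_id"
    if gm.species_id is not None:
        out.insert(0, "species_id", gm.species_id)
    return out
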