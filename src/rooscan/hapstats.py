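"""Frequency-spectrum and haplotype-based selection statistics.

Implements the statistics used to scan a focal promoter-flanking region in a
panel of phased (haploid-coded, inbred) strains: segregating sites, nucleotide
diversity, Tajima's D, extended haplotype homozygosity (EHH) and its integral
(iHH), the standardized iHS and nSL scores, cross-panel XP-EHH, and the
H1/H12/H2 haplotype-homozygosity spectrum of Garud-style soft-sweep scans.

All statistics operate on a :class:`HaplotypeMatrix`: an n x m binary matrix
(0 = ancestral/reference, 1 = derived/alternate) over strictly increasing
1-based bp positions. Missing data is resolved before matrix construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numba
import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeMatrix",
    "SiteFilterSpec",
    "EHHProfile",
    "HaplotypeSpectrum",
    "apply_site_filter",
    "segregating_sites",
    "nucleotide_diversity",
    "tajimas_d",
    "tajima_constants",
    "ehh",
    "ihh",
    "ihs_unstandardized",
    "ihs_scan",
    "FrequencyBins",
    "standardize_by_frequency",
    "nsl_scan",
    "xpehh_unstandardized",
    "xpehh_scan",
    "haplotype_spectrum",
    "h12_scan",
]


@dataclass(frozen=True)
class HaplotypeMatrix:
    """Phased binary haplotypes over polymorphic sites.

    Parameters
    ----------
    alleles : (n, m) array of {0, 1}
        One row per haplotype (= per inbred strain), one column per site.
        0 is the ancestral/reference allele, 1 the derived/alternate allele.
    positions : (m,) array of int
        Strictly increasing 1-based bp coordinates.
    chrom : str
        Contig label.
    strain_ids : sequence of str, optional
        Row labels; generated as ``hap0..hap{n-1}`` when omitted.
    """

    alleles: np.ndarray
    positions: np.ndarray
    chrom: str = "2R"
    strain_ids: tuple = field(default=None)

    def __post_init__(self):
        alleles = np.asarray(self.alleles, dtype=np.int8)
        if alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if alleles.shape[0] < 2:
            raise ValueError("need at least 2 haplotypes")
        if not np.isin(alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1 (resolve missing data first)")
        positions = np.asarray(self.positions, dtype=np.int64)
        if positions.shape != (alleles.shape[1],):
            raise ValueError("positions must match the number of sites")
        if positions.size and not (np.diff(positions) > 0).all():
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "alleles", alleles)
        object.__setattr__(self, "positions", positions)
        ids = self.strain_ids
        if ids is None:
            ids = tuple(f"hap{i}" for i in range(alleles.shape[0]))
        else:
            ids = tuple(str(s) for s in ids)
            if len(ids) != alleles.shape[0]:
                raise ValueError("strain_ids must match the number of haplotypes")
        object.__setattr__(self, "strain_ids", ids)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def take_strains(self, index: Sequence) -> "HaplotypeMatrix":
        """Subset rows by integer index or strain id."""
        idx = []
        for i in index:
            if isinstance(i, str):
                idx.append(self.strain_ids.index(i))
            else:
                idx.append(int(i))
        idx = np.asarray(idx, dtype=int)
        return HaplotypeMatrix(
            self.alleles[idx], self.positions, self.chrom,
            tuple(self.strain_ids[i] for i in idx),
        )

    def take_sites(self, mask_or_index) -> "HaplotypeMatrix":
        """Subset columns (sites), preserving order."""
        arr = np.asarray(mask_or_index)
        return HaplotypeMatrix(
            self.alleles[:, arr], self.positions[arr], self.chrom, self.strain_ids
        )

    def slice_region(self, start: int, end: int) -> "HaplotypeMatrix":
        """Sites with 1-based position in [start, end)."""
        mask = (self.positions >= start) & (self.positions < end)
        return self.take_sites(mask)


@dataclass(frozen=True)
class SiteFilterSpec:
    """Site filters applied before any statistic.

    ``maf_threshold=None`` means the sample-size-dependent default 1/(2n).
    Indel records are removed by default; the comparison for the MAF cut is
    >= (keep when equal).
    """

    maf_threshold: float | None = None
    drop_indels: bool = True

    def resolved_threshold(self, n: int) -> float:
        t = self.maf_threshold if self.maf_threshold is not None else 1.0 / (2 * n)
        if not 0 <= t <= 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5]")
        return t


def apply_site_filter(
    hm: HaplotypeMatrix,
    spec: SiteFilterSpec = SiteFilterSpec(),
    variant_kinds: Sequence[str] | None = None,
) -> HaplotypeMatrix:
    """Keep SNP sites with minor allele frequency >= threshold; drop indels.

    ``variant_kinds`` is a per-site vector of "snp"/"indel"; when omitted all
    sites are treated as SNPs. Monomorphic sites (minor count 0) are always
    removed. Position order is preserved; an empty result is allowed.
    """
    n = hm.n_haplotypes
    freq = hm.alleles.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    thr = spec.resolved_threshold(n)
    keep = (maf > 0) & (maf >= thr)
    if variant_kinds is not None:
        kinds = np.asarray(variant_kinds)
        if kinds.shape != (hm.n_sites,):
            raise ValueError("variant_kinds must align with sites")
        if spec.drop_indels:
            keep &= kinds == "snp"
    return hm.take_sites(keep)


def segregating_sites(hm: HaplotypeMatrix) -> int:
    """Number of sites at which both alleles are present."""
    counts = hm.alleles.sum(axis=0)
    return int(((counts > 0) & (counts < hm.n_haplotypes)).sum())


def nucleotide_diversity(hm: HaplotypeMatrix) -> float:
    """Mean pairwise differences (pi) over all unordered haplotype pairs.

    Computed from per-site allele frequencies as
    sum_sites 2 p (1-p) n/(n-1), which equals the all-pairs Hamming mean.
    """
    n = hm.n_haplotypes
    p = hm.alleles.mean(axis=0)
    return float((2 * p * (1 - p)).sum() * n / (n - 1))


def tajima_constants(n: int) -> dict:
    """The a1/a2/b1/b2/c1/c2/e1/e2 constants of Tajima's D for sample size n."""
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(hm: HaplotypeMatrix) -> float:
    """Tajima's D: normalized difference between pi and Watterson's theta.

    Returns NaN (with a warning) when there are no segregating sites, where
    the statistic is undefined.
    """
    s = segregating_sites(hm)
    if s == 0:
        warnings.warn("Tajima's D undefined with 0 segregating sites", stacklevel=2)
        return float("nan")
    c = tajima_constants(hm.n_haplotypes)
    pi = nucleotide_diversity(hm)
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    return float((pi - s / c["a1"]) / np.sqrt(var))


# ---------------------------------------------------------------------------
# EHH family
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EHHProfile:
    """EHH decay outward from a core site, one grid per direction.

    ``left``/``right`` are (distance, ehh) arrays; distance is measured from
    the core in the profile's coordinate system (bp for iHS/XP-EHH, number of
    segregating sites for nSL) and is 0 at the core where EHH = 1.
    """

    core_position: int
    core_allele: int
    left: np.ndarray   # (k, 2): distance (<= 0), ehh
    right: np.ndarray  # (k, 2): distance (>= 0), ehh
    n_carriers: int


@numba.njit(cache=True)
def _ehh_walk_kernel(alleles, coords, core, step, decay_cutoff, max_gap):  # pragma: no cover
    """Incremental identity-class walk from a core site (compiled).

    Each step splits every haplotype class by the new site's allele and
    relabels compactly (class ids stay below n, so keys stay below 2n);
    EHH is sum c_h(c_h - 1) / (n(n - 1)) over class sizes c_h.
    """
    n, m = alleles.shape
    dist = np.empty(m + 1)
    eh = np.empty(m + 1)
    dist[0] = 0.0
    eh[0] = 1.0
    k = 1
    groups = np.zeros(n, dtype=np.int64)
    counts = np.zeros(2 * n, dtype=np.int64)
    newid = np.zeros(2 * n, dtype=np.int64)
    n_groups = 1
    denom = float(n * (n - 1))
    j = core
    while True:
        j_next = j + step
        if j_next < 0 or j_next >= m:
            break
        if abs(coords[j_next] - coords[j]) > max_gap:
            break
        for i in range(2 * n_groups):
            counts[i] = 0
        for i in range(n):
            key = groups[i] * 2 + alleles[i, j_next]
            groups[i] = key
            counts[key] += 1
        g = 0
        ssum = 0
        for i in range(2 * n_groups):
            if counts[i] > 0:
                newid[i] = g
                g += 1
                ssum += counts[i] * (counts[i] - 1)
        for i in range(n):
            groups[i] = newid[groups[i]]
        n_groups = g
        e = ssum / denom
        dist[k] = coords[j_next] - coords[core]
        eh[k] = e
        k += 1
        if e < decay_cutoff:
            break
        j = j_next
    return dist[:k], eh[:k]


def _ehh_one_side(
    alleles: np.ndarray,
    coords: np.ndarray,
    core: int,
    step: int,
    decay_cutoff: float,
    max_gap: float | None,
) -> np.ndarray:
    """Walk from the core outward in direction ``step`` (+1/-1).

    Haplotypes are grouped by identity on the closed interval [core, x];
    the walk stops when EHH drops below ``decay_cutoff`` or a coordinate gap
    larger than ``max_gap`` is crossed.
    """
    alleles = np.ascontiguousarray(alleles, dtype=np.int8)
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    gap = np.inf if max_gap is None else float(max_gap)
    dist, eh = _ehh_walk_kernel(alleles, coords, int(core), int(step),
                                float(decay_cutoff), gap)
    return np.column_stack([dist, eh])


def ehh(
    hm: HaplotypeMatrix,
    core_site: int,
    allele: int,
    decay_cutoff: float = 0.05,
    max_gap: float | None = 200_000,
    coords: np.ndarray | None = None,
) -> EHHProfile:
    """Extended haplotype homozygosity profile for one core allele.

    EHH at extension site x is the probability that two randomly chosen
    carrier haplotypes are identical over every site in the closed interval
    [core, x]. Computed separately leftward and rightward; truncated when it
    falls below ``decay_cutoff`` or when a gap wider than ``max_gap`` (in the
    coordinate system of ``coords``) is crossed. Pass ``coords`` = site index
    to obtain the nSL distance convention.
    """
    carriers = hm.alleles[:, core_site] == allele
    n_c = int(carriers.sum())
    if n_c < 2:
        raise ValueError("EHH undefined with fewer than 2 core-allele carriers")
    sub = hm.alleles[carriers]
    if coords is None:
        coords = hm.positions.astype(float)
    left = _ehh_one_side(sub, coords, core_site, -1, decay_cutoff, max_gap)
    right = _ehh_one_side(sub, coords, core_site, +1, decay_cutoff, max_gap)
    return EHHProfile(
        core_position=int(hm.positions[core_site]),
        core_allele=int(allele),
        left=left,
        right=right,
        n_carriers=n_c,
    )


def ihh(profile: EHHProfile) -> float:
    """Integrated EHH: trapezoidal integral against distance, both sides summed."""
    total = 0.0
    for side in (profile.left, profile.right):
        if side.shape[0] < 2:
            continue
        d = np.abs(side[:, 0])
        e = side[:, 1]
        total += float(np.trapezoid(e, d))
    return total


def _site_ihh_ratio(
    hm: HaplotypeMatrix,
    site: int,
    coords: np.ndarray,
    decay_cutoff: float,
    max_gap: float | None,
) -> float | None:
    """ln(iHH_derived / iHH_ancestral) at one core site, or None if dropped."""
    col = hm.alleles[:, site]
    n1 = int(col.sum())
    n0 = hm.n_haplotypes - n1
    if n1 < 2 or n0 < 2:
        return None
    ihh_d = ihh(ehh(hm, site, 1, decay_cutoff, max_gap, coords))
    ihh_a = ihh(ehh(hm, site, 0, decay_cutoff, max_gap, coords))
    if ihh_d <= 0 or ihh_a <= 0:
        return None
    return float(np.log(ihh_d / ihh_a))


def ihs_unstandardized(
    hm: HaplotypeMatrix,
    min_maf: float = 0.05,
    decay_cutoff: float = 0.05,
    max_gap: float | None = 200_000,
    coords: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-site unstandardized iHS (ln iHH_derived/iHH_ancestral) and DAF.

    Sites with core MAF < ``min_maf``, fewer than 2 carriers of either allele,
    or a zero integral on either side are dropped.
    """
    if coords is None:
        coords = hm.positions.astype(float)
    rows = []
    freq = hm.alleles.mean(axis=0)
    for j in range(hm.n_sites):
        daf = freq[j]
        if min(daf, 1 - daf) < min_maf:
            continue
        u = _site_ihh_ratio(hm, j, coords, decay_cutoff, max_gap)
        if u is None:
            continue
        rows.append((int(hm.positions[j]), float(daf), u))
    return pd.DataFrame(rows, columns=["position", "daf", "uihs"])


@dataclass(frozen=True)
class FrequencyBins:
    """Derived-frequency bin standardization fitted on a background set.

    Equal-width bins on [0, 1] are merged left to right until each populated
    group holds at least ``min_bin_count`` background sites (the undersized
    tail folds into the previous group); each group stores the background mean
    and sd of the unstandardized score. Fit once on (mostly neutral)
    background sites, then apply to any window — the standard genome-wide
    standardization of haplotype-score scans.
    """

    edges: np.ndarray
    group_of_bin: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def fit(cls, daf, values, n_bins: int = 50, min_bin_count: int = 20):
        daf = np.asarray(daf, dtype=float)
        values = np.asarray(values, dtype=float)
        edges = np.linspace(0, 1, n_bins + 1)
        raw_bin = np.clip(np.digitize(daf, edges[1:-1]), 0, n_bins - 1)
        group_of_bin = np.zeros(n_bins, dtype=int)
        g = 0
        acc = 0
        for b in range(n_bins):
            group_of_bin[b] = g
            acc += int((raw_bin == b).sum())
            if acc >= min_bin_count:
                g += 1
                acc = 0
        if acc > 0 and g > 0:
            group_of_bin[group_of_bin == g] = g - 1
        groups = group_of_bin[raw_bin]
        n_groups = int(group_of_bin.max()) + 1
        means = np.zeros(n_groups)
        sds = np.ones(n_groups)
        for gid in range(n_groups):
            sel = groups == gid
            if sel.any():
                means[gid] = values[sel].mean()
                sds[gid] = values[sel].std()
        return cls(edges, group_of_bin, means, sds)

    def groups_of(self, daf) -> np.ndarray:
        n_bins = self.group_of_bin.shape[0]
        raw = np.clip(np.digitize(np.asarray(daf, float), self.edges[1:-1]),
                      0, n_bins - 1)
        return self.group_of_bin[raw]

    def apply(self, daf, values) -> np.ndarray:
        groups = self.groups_of(daf)
        mu = self.means[groups]
        sd = self.sds[groups]
        out = np.where(sd > 0, (np.asarray(values, float) - mu)
                       / np.where(sd > 0, sd, 1.0), 0.0)
        return out


def standardize_by_frequency(
    daf: np.ndarray,
    values: np.ndarray,
    n_bins: int = 50,
    min_bin_count: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize values to mean 0 / sd 1 within derived-frequency bins.

    Fits the bins on the supplied sites themselves (self-standardization, as
    used within one scan). Returns (standardized, group ids).
    """
    bins = FrequencyBins.fit(daf, values, n_bins, min_bin_count)
    return bins.apply(daf, values), bins.groups_of(daf)


def ihs_scan(
    hm: HaplotypeMatrix,
    min_maf: float = 0.05,
    decay_cutoff: float = 0.05,
    max_gap: float | None = 200_000,
    n_bins: int = 50,
    min_bin_count: int = 20,
) -> pd.DataFrame:
    """Standardized iHS per qualifying core site.

    uiHS = ln(iHH_derived / iHH_ancestral), standardized to mean 0 / sd 1
    within derived-allele-frequency bins. Columns: position, daf, uihs, ihs,
    freq_bin.
    """
    df = ihs_unstandardized(hm, min_maf, decay_cutoff, max_gap)
    if df.empty:
        warnings.warn("iHS scan produced no qualifying sites", stacklevel=2)
        df["ihs"] = pd.Series(dtype=float)
        df["freq_bin"] = pd.Series(dtype=int)
        return df
    std, groups = standardize_by_frequency(
        df["daf"].to_numpy(), df["uihs"].to_numpy(), n_bins, min_bin_count
    )
    df["ihs"] = std
    df["freq_bin"] = groups
    return df


def nsl_scan(
    hm: HaplotypeMatrix,
    min_maf: float = 0.05,
    n_bins: int = 50,
    min_bin_count: int = 20,
) -> pd.DataFrame:
    """Standardized nSL: the iHS pipeline with distance counted in sites.

    Each SNP contributes unit distance (no bp-gap truncation), making the
    statistic robust to recombination/mutation rate variation along the
    region. Columns as in :func:`ihs_scan` with ``unsl``/``nsl``.
    """
    coords = np.arange(hm.n_sites, dtype=float)
    df = ihs_unstandardized(hm, min_maf, decay_cutoff=0.05, max_gap=None,
                            coords=coords)
    df = df.rename(columns={"uihs": "unsl"})
    if df.empty:
        warnings.warn("nSL scan produced no qualifying sites", stacklevel=2)
        df["nsl"] = pd.Series(dtype=float)
        df["freq_bin"] = pd.Series(dtype=int)
        return df
    std, groups = standardize_by_frequency(
        df["daf"].to_numpy(), df["unsl"].to_numpy(), n_bins, min_bin_count
    )
    df["nsl"] = std
    df["freq_bin"] = groups
    return df


def _panel_ihh(hm: HaplotypeMatrix, site: int, decay_cutoff: float,
               max_gap: float | None) -> float:
    """iHH over all haplotypes of a panel (no allele split), as in XP-EHH."""
    coords = hm.positions.astype(float)
    left = _ehh_one_side(hm.alleles, coords, site, -1, decay_cutoff, max_gap)
    right = _ehh_one_side(hm.alleles, coords, site, +1, decay_cutoff, max_gap)
    prof = EHHProfile(int(hm.positions[site]), -1, left, right, hm.n_haplotypes)
    return ihh(prof)


def xpehh_unstandardized(
    hmA: HaplotypeMatrix,
    hmB: HaplotypeMatrix,
    decay_cutoff: float = 0.05,
    max_gap: float | None = 200_000,
) -> pd.DataFrame:
    """Per-site ln(iHH_A / iHH_B) using all haplotypes of each panel.

    Positive values indicate longer haplotype homozygosity in panel A. Both
    panels must carry the same sites at the same positions.
    """
    if hmA.n_sites != hmB.n_sites or not np.array_equal(hmA.positions, hmB.positions):
        posA, posB = set(hmA.positions.tolist()), set(hmB.positions.tolist())
        diff = sorted(posA.symmetric_difference(posB))
        first = diff[0] if diff else hmA.positions[0]
        raise ValueError(f"panels disagree on site sets (first mismatch at {first})")
    rows = []
    for j in range(hmA.n_sites):
        a = _panel_ihh(hmA, j, decay_cutoff, max_gap)
        b = _panel_ihh(hmB, j, decay_cutoff, max_gap)
        if a <= 0 or b <= 0:
            continue
        rows.append((int(hmA.positions[j]), float(np.log(a / b))))
    return pd.DataFrame(rows, columns=["position", "uxpehh"])


def xpehh_scan(
    hmA: HaplotypeMatrix,
    hmB: HaplotypeMatrix,
    decay_cutoff: float = 0.05,
    max_gap: float | None = 200_000,
) -> pd.DataFrame:
    """XP-EHH standardized to mean 0 / sd 1 over all scanned sites."""
    df = xpehh_unstandardized(hmA, hmB, decay_cutoff, max_gap)
    if df.empty:
        df["xpehh"] = pd.Series(dtype=float)
        return df
    v = df["uxpehh"].to_numpy()
    sd = v.std()
    df["xpehh"] = 0.0 if sd == 0 else (v - v.mean()) / sd
    return df


# ---------------------------------------------------------------------------
# Haplotype homozygosity spectrum (H1 / H12 / H2)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeSpectrum:
    """Sorted haplotype frequencies over a SNP window plus H-statistics."""

    window: tuple
    hap_frequencies: np.ndarray  # descending
    h1: float
    h12: float
    h2: float


def haplotype_spectrum(hm: HaplotypeMatrix, window: tuple[int, int]) -> HaplotypeSpectrum:
    """Group identical haplotype strings over a half-open site-index window.

    H1 = sum p_i^2; H12 = (p1 + p2)^2 + sum_{i>=3} p_i^2 (pools the two most
    frequent haplotypes, sensitive to both hard and soft sweeps); H2 = H1 - p1^2.
    Sorting is by (frequency desc, haplotype string asc) so results are
    deterministic under ties.
    """
    start, stop = window
    if start < 0 or stop > hm.n_sites or start >= stop:
        raise ValueError("window out of site range")
    sub = hm.alleles[:, start:stop]
    strings = ["".join(map(str, row)) for row in sub]
    ser = pd.Series(strings).value_counts()
    order = sorted(ser.items(), key=lambda kv: (-kv[1], kv[0]))
    counts = np.array([c for _, c in order], dtype=float)
    p = counts / counts.sum()
    h1 = float((p**2).sum())
    p1 = p[0]
    p2 = p[1] if len(p) > 1 else 0.0
    h12 = float((p1 + p2) ** 2 + (p[2:] ** 2).sum())
    h2 = h1 - p1**2
    return HaplotypeSpectrum((start, stop), p, h1, h12, h2)


def h12_scan(hm: HaplotypeMatrix, window_size: int = 40, step: int = 1) -> pd.DataFrame:
    """Sliding-window H1/H12/H2 over the whole matrix.

    Window width is in segregating sites (40 by default); step in sites.
    Columns: start, stop (site indices), center_bp, h1, h12, h2.
    """
    if window_size > hm.n_sites:
        raise ValueError("window wider than available sites")
    rows = []
    for start in range(0, hm.n_sites - window_size + 1, step):
        stop = start + window_size
        sp = haplotype_spectrum(hm, (start, stop))
        center = int(hm.positions[start : stop].mean())
        rows.append((start, stop, center, sp.h1, sp.h12, sp.h2))
    return pd.DataFrame(rows, columns=["start", "stop", "center_bp", "h1", "h12", "h2"])
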