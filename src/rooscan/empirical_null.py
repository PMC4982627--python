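"""Significance machinery: resampling and empirical chromosome-wide nulls.

Significance of the region statistics is assessed without a parametric model:

* the number of segregating sites in a carrier subset is compared against the
  distribution obtained by repeatedly resampling the same number of strains
  from the full panel (strain-resampling null);
* Tajima's D, H12, |iHS|, |nSL| and XP-EHH are compared against their
  empirical distributions over many background windows, standing in for the
  chromosome-wide empirical distribution.

Empirical p-values use the add-one convention (r + 1)/(N + 1), so p is never
exactly 0 and is uniform on its attainable grid under the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import hapstats
from .hapstats import HaplotypeMatrix
from .synthetic_data import Panel

__all__ = [
    "EmpiricalNull",
    "PartitionSpec",
    "resample_segregating_sites",
    "build_background_null",
    "empirical_pvalue",
    "partitioned_scan",
]


@dataclass(frozen=True)
class EmpiricalNull:
    """A sorted vector of null values for one statistic."""

    statistic_name: str
    values: np.ndarray
    source: str  # "chromosome_background" | "strain_resampling"

    def __post_init__(self):
        v = np.sort(np.asarray(self.values, dtype=float))
        if v.size == 0:
            raise ValueError("empirical null must hold at least one value")
        object.__setattr__(self, "values", v)
        if v.size < 100:
            warnings.warn(
                f"null for {self.statistic_name} has only {v.size} values; "
                "p-values will be coarse", stacklevel=2,
            )

    @property
    def n_values(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class PartitionSpec:
    """Carrier / non-carrier strain partition for a focal insertion.

    ``carriers`` hold the focal insertion; ``any_insertion_carriers`` hold any
    of the characterized insertions (a superset of carriers);
    ``non_carriers`` hold none. Region is (chrom, start, end) half-open bp.
    """

    focal_insertion: str
    carriers: tuple
    any_insertion_carriers: tuple
    non_carriers: tuple
    region: tuple = ("2R", 0, 2_000_000_000)

    def __post_init__(self):
        carriers = set(self.carriers)
        any_c = set(self.any_insertion_carriers)
        non = set(self.non_carriers)
        if not carriers <= any_c:
            raise ValueError("carriers must be a subset of any_insertion_carriers")
        if any_c & non:
            raise ValueError("insertion carriers and non-carriers must be disjoint")
        chrom, start, end = self.region
        if start > end:
            raise ValueError("malformed region")


def resample_segregating_sites(
    hm: HaplotypeMatrix,
    k: int,
    n_reps: int = 10_000,
    seed: int = 0,
) -> EmpiricalNull:
    """Null distribution of S from random k-strain subsets of the panel.

    Strains are drawn without replacement ``n_reps`` times and S recomputed on
    the (already filtered) sites each time. With k equal to the panel size the
    null is degenerate at the observed S.
    """
    n = hm.n_haplotypes
    if k > n:
        raise ValueError("subset size exceeds panel size")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_reps)
    alleles = hm.alleles
    for r in range(n_reps):
        idx = rng.choice(n, size=k, replace=False)
        sub = alleles[idx]
        counts = sub.sum(axis=0)
        vals[r] = int(((counts > 0) & (counts < k)).sum())
    return EmpiricalNull("S", vals, "strain_resampling")


def build_background_null(stat: str, values) -> EmpiricalNull:
    """Collect a statistic over background windows into an empirical null."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no background values supplied")
    return EmpiricalNull(stat, arr, "chromosome_background")


def empirical_pvalue(observed: float, null: EmpiricalNull, tail: str = "upper") -> float:
    """Add-one empirical p-value against a null vector.

    upper: (#{null >= observed} + 1)/(N + 1); lower analogous;
    two_sided: 2 * min(lower, upper), capped at 1.
    """
    v = null.values
    n = v.size
    upper = (float((v >= observed).sum()) + 1) / (n + 1)
    lower = (float((v <= observed).sum()) + 1) / (n + 1)
    if tail == "upper":
        return upper
    if tail == "lower":
        return lower
    if tail == "two_sided":
        return min(1.0, 2 * min(lower, upper))
    raise ValueError(f"unknown tail {tail!r}")


# ---------------------------------------------------------------------------
# Partitioned scans
# ---------------------------------------------------------------------------

def _strain_indices(hm: HaplotypeMatrix, strains) -> np.ndarray:
    return np.array([hm.strain_ids.index(s) for s in strains], dtype=int)


def _max_abs_standardized(
    focal_u: np.ndarray,
    focal_daf: np.ndarray,
    bg_u: list[np.ndarray],
    bg_daf: list[np.ndarray],
) -> tuple[float, np.ndarray]:
    """Standardize pooled (background + focal) scores in frequency bins.

    Returns (max |score| in the focal window, per-background-window max
    |score|) so focal and null summaries share one standardization.
    """
    all_u = np.concatenate([focal_u] + bg_u) if bg_u else focal_u
    all_daf = np.concatenate([focal_daf] + bg_daf) if bg_daf else focal_daf
    if all_u.size == 0:
        return np.nan, np.array([])
    std, _ = hapstats.standardize_by_frequency(all_daf, all_u)
    n_focal = focal_u.size
    focal_std = std[:n_focal]
    focal_max = float(np.abs(focal_std).max()) if n_focal else np.nan
    bg_max = []
    k = n_focal
    for u in bg_u:
        seg = std[k : k + u.size]
        bg_max.append(float(np.abs(seg).max()) if u.size else np.nan)
        k += u.size
    return focal_max, np.asarray(bg_max)


def partitioned_scan(
    panel: Panel,
    part: PartitionSpec,
    background_windows: list[HaplotypeMatrix],
    h12_window: int = 40,
    n_resample: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Carrier/non-carrier partitioned selection scan with empirical p-values.

    For each carrier set (focal-insertion carriers, then any-insertion
    carriers) the scan computes, over the focal region:

    * S with a strain-resampling null (lower tail: reduced diversity);
    * Tajima's D against the background-window null (lower tail);
    * max window H12 against the background null (upper tail);
    * max |iHS| and |nSL| (pooled-standardized with the background; upper);
    * XP-EHH between the carrier set (A) and the non-carriers (B), max value
      against per-background permuted-label ratios (upper tail).

    Returns a tidy frame (partition, statistic, value, p_value, tail, n_null).
    """
    hm = panel.haplotypes
    chrom, start, end = part.region
    region = hm.slice_region(start, end)
    rng = np.random.default_rng(seed)

    partitions = {
        "focal_carriers": tuple(part.carriers),
        "any_insertion_carriers": tuple(part.any_insertion_carriers),
    }
    non_idx = _strain_indices(hm, part.non_carriers)
    rows = []
    for pname, strains in partitions.items():
        if len(strains) < 2 or len(part.non_carriers) < 2:
            raise ValueError(f"partition {pname} needs >= 2 strains on each side")
        idx = _strain_indices(hm, strains)
        sub = region.take_strains(idx)

        # S: strain-resampling null over the full panel in the same region
        s_obs = float(hapstats.segregating_sites(sub))
        s_null = resample_segregating_sites(region, k=len(strains),
                                            n_reps=n_resample,
                                            seed=int(rng.integers(2**31)))
        rows.append((pname, "S", s_obs, empirical_pvalue(s_obs, s_null, "lower"),
                     "lower", s_null.n_values))

        # background windows restricted to the same strain subset
        bg_subs = [w.take_strains(idx) for w in background_windows]

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d_obs = hapstats.tajimas_d(sub)
            d_bg = [hapstats.tajimas_d(w) for w in bg_subs]
        d_null = build_background_null("tajimas_d", d_bg)
        d_p = (np.nan if np.isnan(d_obs)
               else empirical_pvalue(d_obs, d_null, "lower"))
        rows.append((pname, "tajimas_d", d_obs, d_p, "lower", d_null.n_values))

        def max_h12(m):
            w = min(h12_window, m.n_sites)
            if w < 1:
                return np.nan
            scan = hapstats.h12_scan(m, window_size=w, step=max(1, w // 2))
            return float(scan["h12"].max()) if len(scan) else np.nan

        h_obs = max_h12(sub)
        h_null = build_background_null("H12", [max_h12(w) for w in bg_subs])
        h_p = (np.nan if np.isnan(h_obs)
               else empirical_pvalue(h_obs, h_null, "upper"))
        rows.append((pname, "H12", h_obs, h_p, "upper", h_null.n_values))

        # iHS / nSL: pooled standardization across background + focal sites
        for stat, kwargs in (("ihs", {}), ("nsl", {"coords": "index"})):
            def unstd(m):
                if kwargs.get("coords") == "index":
                    coords = np.arange(m.n_sites, dtype=float)
                    return hapstats.ihs_unstandardized(m, coords=coords,
                                                       max_gap=None)
                return hapstats.ihs_unstandardized(m)

            f = unstd(sub)
            bg = [unstd(w) for w in bg_subs]
            obs, bg_max = _max_abs_standardized(
                f["uihs"].to_numpy(), f["daf"].to_numpy(),
                [b["uihs"].to_numpy() for b in bg],
                [b["daf"].to_numpy() for b in bg],
            )
            bg_max = bg_max[~np.isnan(bg_max)]
            if np.isnan(obs) or bg_max.size == 0:
                rows.append((pname, stat, np.nan, np.nan, "upper", 0))
            else:
                null = build_background_null(stat, bg_max)
                rows.append((pname, stat, obs,
                             empirical_pvalue(obs, null, "upper"), "upper",
                             null.n_values))

        # XP-EHH carriers (A) vs non-carriers (B); null from background windows
        sub_b = region.take_strains(non_idx)
        xp = hapstats.xpehh_unstandardized(sub, sub_b)
        xp_bg = []
        for w in background_windows:
            wa = w.take_strains(idx)
            wb = w.take_strains(non_idx)
            x = hapstats.xpehh_unstandardized(wa, wb)
            if len(x):
                xp_bg.append(float(x["uxpehh"].max()))
        if len(xp) == 0 or not xp_bg:
            rows.append((pname, "xpehh", np.nan, np.nan, "upper", 0))
        else:
            xp_obs = float(xp["uxpehh"].max())
            null = build_background_null("xpehh", xp_bg)
            rows.append((pname, "xpehh", xp_obs,
                         empirical_pvalue(xp_obs, null, "upper"), "upper",
                         null.n_values))

    return pd.DataFrame(
        rows, columns=["partition", "statistic", "value", "p_value", "tail",
                       "n_null"]
    )
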