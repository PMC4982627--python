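"""Synthetic inputs with known ground truth for the whole pipeline.

Generates every input the analyses need: neutral coalescent haplotype panels
(and many-window "chromosome-wide" backgrounds for empirical nulls), sweep
panels in which carrier strains share a forced recent common ancestor,
insertion-genotyped strain panels mimicking a panel of inbred lines each
carrying at most one solo-LTR allele, binomial egg-to-adult viability tables
with condition x genotype x interaction effects, and promoter constructs with
target-site duplications.

The simulator is a Kingman coalescent without recombination (the focal region
is ~2 kb, so intra-window recombination is negligible); the sweep model is a
time-scaling construction — carriers' within-group coalescence times are
multiplied by ``sweep_strength`` in (0, 1], compressing their genealogy and
lengthening shared haplotypes — not a forward selection simulation. Strains
are haploid-coded (inbred lines: one haplotype per strain). All randomness
flows from one explicit seed through ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hapstats import HaplotypeMatrix
from .te_annotation import InsertionRecord

__all__ = [
    "SimConfig",
    "Panel",
    "simulate_coalescent_haplotypes",
    "simulate_sweep_haplotypes",
    "simulate_background_windows",
    "simulate_insertion_panel",
    "simulate_viability_table",
    "build_promoter_construct",
    "random_sequence",
]


@dataclass(frozen=True)
class SimConfig:
    """Panel-simulation settings.

    theta is the population mutation rate per region on the 4Nu scale;
    sweep_strength in (0, 1] scales carrier coalescence times (1 = neutral).
    Identical seeds yield bit-identical output.
    """

    n_strains: int = 25
    region_length: int = 2000
    theta: float = 10.0
    carrier_fraction: float = 0.4
    sweep_strength: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        if self.region_length < 1:
            raise ValueError("region_length must be >= 1")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not 0 <= self.carrier_fraction <= 1:
            raise ValueError("carrier_fraction must be in [0, 1]")
        if not 0 < self.sweep_strength <= 1:
            raise ValueError("sweep_strength must be in (0, 1]")


@dataclass(frozen=True)
class Panel:
    """A simulated strain panel: haplotypes plus per-strain insertion genotype."""

    haplotypes: HaplotypeMatrix
    strain_ids: tuple
    insertion_genotype: tuple  # per strain: insertion id or "none"
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.strain_ids) != self.haplotypes.n_haplotypes:
            raise ValueError("strain count must match haplotype rows")
        if len(self.insertion_genotype) != len(self.strain_ids):
            raise ValueError("one genotype entry per strain required")

    def strains_with(self, insertion_id: str) -> tuple:
        return tuple(
            s for s, g in zip(self.strain_ids, self.insertion_genotype)
            if g == insertion_id
        )

    def carriers_of_any(self, insertion_ids) -> tuple:
        ids = set(insertion_ids)
        return tuple(
            s for s, g in zip(self.strain_ids, self.insertion_genotype) if g in ids
        )


# ---------------------------------------------------------------------------
# Coalescent machinery
# ---------------------------------------------------------------------------

def _kingman_tree(n: int, rng: np.random.Generator, time_scale: float = 1.0):
    """Random-topology Kingman tree on n leaves.

    Returns (parent, node_time) arrays over 2n-1 nodes; leaves are 0..n-1 at
    time 0, the root is the last node. Inter-coalescence waiting times are
    Exp(k(k-1)/2) multiplied by ``time_scale``.
    """
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += time_scale * rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        # O(1) removal: overwrite the merged pair with the new node + the tail
        hi, lo = (i, j) if i > j else (j, i)
        active[lo] = nxt
        active[hi] = active[-1]
        active.pop()
        nxt += 1
    return parent, node_time


def _leaf_sets(parent: np.ndarray, n_leaves: int) -> list:
    """Descendant-leaf boolean mask per node."""
    n_nodes = parent.shape[0]
    masks = [np.zeros(n_leaves, dtype=bool) for _ in range(n_nodes)]
    for leaf in range(n_leaves):
        masks[leaf][leaf] = True
        p = parent[leaf]
        while p != -1:
            masks[p][leaf] = True
            p = parent[p]
    return masks


def _drop_mutations(
    parent: np.ndarray,
    node_time: np.ndarray,
    n_leaves: int,
    region_length: int,
    theta: float,
    rng: np.random.Generator,
) -> HaplotypeMatrix:
    """Poisson mutations on branches; infinite-sites integer positions.

    The mutation count is Poisson(theta * L_total / 2) with L_total the total
    branch length in coalescent units; each mutation lands on a branch chosen
    proportional to its length, at a uniform real position floored to a
    distinct integer bp (collisions redrawn).
    """
    non_root = parent != -1
    branch_len = np.where(non_root, node_time[parent] - node_time, 0.0)
    total = branch_len.sum()
    n_mut = rng.poisson(theta * total / 2.0) if total > 0 and theta > 0 else 0
    if n_mut > region_length:
        raise ValueError("more mutations than available integer positions")
    alleles = np.zeros((n_leaves, 0), dtype=np.int8)
    if n_mut == 0:
        return HaplotypeMatrix(np.zeros((n_leaves, 0), dtype=np.int8),
                               np.zeros(0, dtype=np.int64))
    probs = branch_len / total
    branches = rng.choice(branch_len.shape[0], size=n_mut, p=probs)
    positions: set[int] = set()
    pos_list = []
    for _ in range(n_mut):
        while True:
            p = int(np.floor(rng.uniform(0, region_length)))
            if p not in positions:
                positions.add(p)
                pos_list.append(p)
                break
    masks = _leaf_sets(parent, n_leaves)
    cols = np.zeros((n_leaves, n_mut), dtype=np.int8)
    for k, br in enumerate(branches):
        cols[:, k] = masks[br]
    order = np.argsort(pos_list)
    pos_sorted = np.asarray(pos_list, dtype=np.int64)[order] + 1  # 1-based
    return HaplotypeMatrix(cols[:, order], pos_sorted)


def simulate_coalescent_haplotypes(
    n: int,
    region_length: int = 2000,
    theta: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> HaplotypeMatrix:
    """Neutral Kingman-coalescent haplotypes without recombination.

    Under this model E[S] = theta * sum_{i<n} 1/i and E[pi] = theta,
    the standard infinite-sites expectations. Ancestral allele is 0.
    """
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parent, node_time = _kingman_tree(n, rng)
    return _drop_mutations(parent, node_time, n, region_length, theta, rng)


def _sweep_tree(
    n: int,
    carrier_mask: np.ndarray,
    sweep_strength: float,
    rng: np.random.Generator,
):
    """Genealogy in which carriers coalesce with time scaled by sweep_strength.

    Carriers first coalesce among themselves (scaled waiting times, forcing a
    recent common ancestor); non-carriers coalesce neutrally from time 0, and
    the carrier ancestor joins the neutral process once it exists.
    """
    n_carriers = int(carrier_mask.sum())
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    nxt = n

    carrier_leaves = list(np.flatnonzero(carrier_mask))
    other_leaves = list(np.flatnonzero(~carrier_mask))

    # stage 1: scaled coalescent among carriers up to their MRCA
    active = list(carrier_leaves)
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += sweep_strength * rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    carrier_root = active[0]
    t_join = node_time[carrier_root] if n_carriers > 1 else 0.0

    # stage 2: neutral coalescent of non-carriers, carrier root joins at t_join
    active = list(other_leaves)
    pending = carrier_root if n_carriers >= 1 else None
    if pending is not None and t_join == 0.0:
        active.append(pending)
        pending = None
    t = 0.0
    while len(active) > 1 or pending is not None:
        k = len(active)
        if k < 2:
            # only the pending lineage can make this a coalescent again
            t = max(t, t_join)
            active.append(pending)
            pending = None
            continue
        wait = rng.exponential(2.0 / (k * (k - 1)))
        if pending is not None and t + wait >= t_join:
            t = t_join
            active.append(pending)
            pending = None
            continue
        t += wait
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return parent, node_time


def simulate_sweep_haplotypes(
    n: int,
    region_length: int = 2000,
    theta: float = 10.0,
    carrier_fraction: float = 0.4,
    sweep_strength: float = 0.05,
    seed: int | np.random.Generator = 0,
    carrier_mask: np.ndarray | None = None,
) -> tuple[HaplotypeMatrix, np.ndarray]:
    """Haplotypes with a sweep-like genealogy among carrier strains.

    round(carrier_fraction * n) strains are carriers (positions drawn at
    random unless ``carrier_mask`` is given); their within-group coalescence
    times are multiplied by ``sweep_strength`` before mutations are dropped,
    so smaller values force longer shared haplotypes. ``sweep_strength=1``
    reduces to a neutral genealogy for the carrier subsample. Returns
    (matrix, carrier flags).
    """
    if not 0 < carrier_fraction <= 1:
        raise ValueError("carrier_fraction must be in (0, 1]")
    if not 0 < sweep_strength <= 1:
        raise ValueError("sweep_strength must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if carrier_mask is None:
        n_carriers = int(round(carrier_fraction * n))
        if n_carriers < 2:
            raise ValueError("degenerate sweep: fewer than 2 carriers")
        carrier_mask = np.zeros(n, dtype=bool)
        carrier_mask[rng.choice(n, size=n_carriers, replace=False)] = True
    else:
        carrier_mask = np.asarray(carrier_mask, dtype=bool)
        if carrier_mask.shape != (n,):
            raise ValueError("carrier_mask must have length n")
        if carrier_mask.sum() < 2:
            raise ValueError("degenerate sweep: fewer than 2 carriers")
    if carrier_mask.all():
        parent, node_time = _kingman_tree(n, rng, time_scale=sweep_strength)
    else:
        parent, node_time = _sweep_tree(n, carrier_mask, sweep_strength, rng)
    hm = _drop_mutations(parent, node_time, n, region_length, theta, rng)
    return hm, carrier_mask


def simulate_background_windows(
    n_windows: int,
    n: int,
    region_length: int = 2000,
    theta: float = 10.0,
    seed: int = 0,
) -> list[HaplotypeMatrix]:
    """Independent neutral windows standing in for a chromosome-wide background.

    Each window is an independent no-recombination coalescent; together they
    play the role of the empirical distribution of a statistic along a
    chromosome arm.
    """
    children = np.random.SeedSequence(seed).spawn(n_windows)
    return [
        simulate_coalescent_haplotypes(n, region_length, theta,
                                       np.random.default_rng(ss))
        for ss in children
    ]


# ---------------------------------------------------------------------------
# Insertion-genotyped panels
# ---------------------------------------------------------------------------

def simulate_insertion_panel(
    config: SimConfig,
    insertion_freqs: dict[str, float],
    focal_insertion: str | None = None,
    seed: int | None = None,
) -> Panel:
    """A strain panel with at most one insertion allele per strain.

    Each strain receives exactly one insertion id (or "none") by a multinomial
    draw from ``insertion_freqs`` (which must sum to 1 together with an
    implicit or explicit "none" class). Carriers of ``focal_insertion`` get
    sweep-structured haplotypes in the focal region (time-scaling
    ``config.sweep_strength``); all other strains evolve neutrally. Ground
    truth (carrier mask, parameters) is recorded on the panel.
    """
    seed = config.seed if seed is None else seed
    freqs = dict(insertion_freqs)
    total = sum(freqs.values())
    if any(not 0 <= f <= 1 for f in freqs.values()):
        raise ValueError("frequencies must be in [0, 1]")
    if "none" not in freqs:
        if total > 1 + 1e-9:
            raise ValueError("insertion frequencies exceed 1")
        freqs["none"] = 1.0 - total
    elif abs(sum(freqs.values()) - 1.0) > 1e-9:
        raise ValueError("frequencies (including 'none') must sum to 1")
    ss = np.random.SeedSequence(seed).spawn(2)
    rng_geno = np.random.default_rng(ss[0])
    rng_hap = np.random.default_rng(ss[1])

    ids = sorted(freqs)
    p = np.array([freqs[i] for i in ids])
    p = p / p.sum()
    draws = rng_geno.choice(len(ids), size=config.n_strains, p=p)
    genotypes = tuple(ids[d] for d in draws)
    strain_ids = tuple(f"S{i:04d}" for i in range(config.n_strains))

    carrier_mask = np.array([g == focal_insertion for g in genotypes])
    if focal_insertion is not None and carrier_mask.sum() >= 2:
        hm, _ = simulate_sweep_haplotypes(
            config.n_strains, config.region_length, config.theta,
            carrier_fraction=carrier_mask.mean() or 1.0,
            sweep_strength=config.sweep_strength,
            seed=rng_hap, carrier_mask=carrier_mask,
        )
    else:
        hm = simulate_coalescent_haplotypes(
            config.n_strains, config.region_length, config.theta, rng_hap
        )
    hm = HaplotypeMatrix(hm.alleles, hm.positions, hm.chrom, strain_ids)
    truth = {
        "focal_insertion": focal_insertion,
        "carrier_mask": carrier_mask,
        "config": config,
        "insertion_freqs": freqs,
    }
    return Panel(hm, strain_ids, genotypes, truth)


# ---------------------------------------------------------------------------
# Viability tables
# ---------------------------------------------------------------------------

def simulate_viability_table(
    effects: dict[str, float],
    n_vials: int = 10,
    embryos_per_vial: int = 30,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Vial-level egg-to-adult viability counts in a balanced 2x2 design.

    ``effects`` has keys baseline/condition/genotype/interaction on the
    arcsine scale: the cell mean is sin(baseline + condition*c + genotype*g +
    interaction*c*g)^2 with c, g in {0, 1} (c = 1 under cold stress, g = 1
    with the insertion). Emerged counts are Binomial(embryos_per_vial, p_cell)
    per vial. The default baseline arcsin(sqrt(0.5)) centers viability at 50%.
    """
    base = effects.get("baseline", float(np.arcsin(np.sqrt(0.5))))
    rng = np.random.default_rng(seed)
    if embryos_per_vial <= 0 or n_vials <= 0:
        raise ValueError("n_vials and embryos_per_vial must be positive")
    rows = []
    for rep in range(1, n_replicates + 1):
        for cond_label, c in (("control", 0), ("cold_stress", 1)):
            for geno_label, g in (("without_insertion", 0), ("with_insertion", 1)):
                a = (base + effects.get("condition", 0.0) * c
                     + effects.get("genotype", 0.0) * g
                     + effects.get("interaction", 0.0) * c * g)
                if not 0 < a < np.pi / 2:
                    raise ValueError(
                        "effects push the arcsine-scale cell mean outside "
                        f"(0, pi/2): {a:.3f} (probability would leave (0, 1))"
                    )
                p = float(np.sin(a) ** 2)
                emerged = rng.binomial(embryos_per_vial, p, size=n_vials)
                for v, e in enumerate(emerged, start=1):
                    rows.append((cond_label, geno_label, f"rep{rep}", f"vial{v}",
                                 int(e), embryos_per_vial))
    return pd.DataFrame(
        rows, columns=["condition", "genotype", "replicate", "vial",
                       "emerged", "total"]
    )


# ---------------------------------------------------------------------------
# Promoter constructs
# ---------------------------------------------------------------------------

def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def build_promoter_construct(
    reference_seq: str,
    rec: InsertionRecord,
    insertion_point: int,
) -> str:
    """Insert an element with its TSD into a reference promoter sequence.

    With reference = P + T + Q (T the target site of len(rec.tsd) bp starting
    at ``insertion_point``), returns P + T + E + T + Q: the element duplicates
    its target site on insertion. The element sequence is reverse-complemented
    for reverse-orientation records.
    """
    tsd_len = len(rec.tsd)
    if insertion_point < 0 or insertion_point + tsd_len > len(reference_seq):
        raise ValueError("TSD extends past the end of the reference sequence")
    if rec.element_seq is None:
        raise ValueError("record carries no element sequence")
    element = rec.element_seq
    from .te_annotation import reverse_complement
    if rec.orientation == "reverse":
        element = reverse_complement(element)
    p = reference_seq[:insertion_point]
    t = reference_seq[insertion_point : insertion_point + tsd_len]
    q = reference_seq[insertion_point + tsd_len :]
    return p + t + element + t + q
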