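"""Sequence-level arithmetic for solo-LTR insertions in a gene promoter.

Covers the annotation layer around a cluster of independent 428-bp roo
solo-LTR insertions near a stress-response gene's transcription start site:

* target-site-duplication (TSD) detection from absent/present allele pairs,
  and the position-frequency "logo" of a TSD collection;
* position-weight-matrix scanning of promoter/LTR sequence with the
  relative-score convention (hits above 0.995 by default usage);
* motif-spacing arithmetic for insertions that fall between regulatory motifs;
* an in-silico PCR band model that reproduces the qualitative genotyping
  classes of a three-primer (FL / L / R) presence-absence assay;
* alternative-TSS transcript 5'-UTR arithmetic for TE-initiated transcripts;
* strand-aware classification of TE insertions as promoter-proximal.

Interval logic is 0-based half-open internally.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "InsertionRecord",
    "TSDLogo",
    "MotifMatrix",
    "AmpliconModel",
    "TranscriptModel",
    "NINE_INSERTIONS",
    "ROO_PLUS7_WITH_DUP",
    "reverse_complement",
    "detect_tsd",
    "build_tsd_logo",
    "scan_pwm",
    "motif_spacing_change",
    "predict_pcr_bands",
    "classify_genotype",
    "transcript_utr_lengths",
    "promoter_5prime_fraction",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC codes for every non-empty base subset
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class InsertionRecord:
    """One solo-LTR insertion allele around the reference position.

    ``offset_bp`` is signed, relative to the reference insertion position
    (positive = downstream, toward the gene). ``extras_flank_dup_bp`` models
    strains carrying an additional duplication of the region immediately
    upstream of the element. ``te_internal_tss`` marks alleles for which the
    element seeds an alternative transcription start site.
    """

    insertion_id: str
    offset_bp: int = 0
    orientation: str = "forward"
    element_length: int = 428
    tsd: str = ""
    extras_flank_dup_bp: int = 0
    te_internal_tss: bool = False
    element_seq: str | None = None

    def __post_init__(self):
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")
        if self.element_length <= 0:
            raise ValueError("element_length must be positive")
        if self.element_seq is not None and len(self.element_seq) != self.element_length:
            raise ValueError("element_seq length disagrees with element_length")


#: The nine independent solo-LTR alleles characterized around the reference
#: position: three downstream (+7/+175/+278), five upstream, four of which
#: (-19/-28/-44/-68) are inserted in reverse orientation. TSD lengths follow
#: the characterized alleles (typically 5 nt; 2 nt for +7, 4 nt for -19, none
#: recovered for +278) — the letter content here is synthetic placeholder
#: sequence. Only the reference element and the +7 element seed a TE-internal
#: TSS.
NINE_INSERTIONS: tuple[InsertionRecord, ...] = (
    InsertionRecord("reference", 0, "forward", tsd="AATAC", te_internal_tss=True),
    InsertionRecord("roo+7", 7, "forward", tsd="TA", te_internal_tss=True),
    InsertionRecord("roo+175", 175, "forward", tsd="CTTAA"),
    InsertionRecord("roo+278", 278, "forward", tsd=""),
    InsertionRecord("roo-19", -19, "reverse", tsd="ATGC"),
    InsertionRecord("roo-28", -28, "reverse", tsd="TTAGT"),
    InsertionRecord("roo-44", -44, "reverse", tsd="CAGTT"),
    InsertionRecord("roo-68", -68, "reverse", tsd="GTTAC"),
    InsertionRecord("roo-90", -90, "forward", tsd="TCAAG"),
)

#: Strain-level variant of the +7 allele carrying an additional 95-bp
#: duplication of the region immediately upstream of the element.
ROO_PLUS7_WITH_DUP = InsertionRecord(
    "roo+7dup", 7, "forward", tsd="TA", extras_flank_dup_bp=95,
    te_internal_tss=True,
)


# ---------------------------------------------------------------------------
# TSD detection and logo
# ---------------------------------------------------------------------------

def detect_tsd(absent_allele: str, present_allele: str) -> tuple[str, int, str]:
    """Recover the TSD, insertion point and element from an allele pair.

    Finds the decomposition absent = P + T + Q, present = P + T + E + T + Q
    maximizing |T| (leftmost insertion point on ties). Returns
    ``(tsd, insertion_point, element_seq)`` with the 0-based insertion point
    at the start of T in the absent allele; the TSD may be empty.
    """
    absent, present = absent_allele.upper(), present_allele.upper()
    if len(present) <= len(absent):
        raise ValueError("present allele must be longer than the absent allele")
    e_len = len(present) - len(absent)
    # common prefix / suffix lengths bound the admissible split points
    a = 0
    while a < len(absent) and absent[a] == present[a]:
        a += 1
    b = 0
    while b < len(absent) and absent[-1 - b] == present[-1 - b]:
        b += 1
    lo = len(absent) - b
    if lo > a:
        raise ValueError("no insertion decomposition: flanks do not align")
    best_t, best_i = -1, -1
    for i in range(lo, a + 1):  # present = absent[:i] + ins + absent[i:]
        ins = present[i : i + e_len]
        t_max = min(i, e_len)
        t = 0
        # longest suffix of ins equal to the absent prefix ending at i
        for k in range(t_max, -1, -1):
            if k == 0 or absent[i - k : i] == ins[e_len - k :]:
                t = k
                break
        if t > best_t:
            best_t, best_i = t, i
    ins = present[best_i : best_i + e_len]
    tsd = absent[best_i - best_t : best_i]
    element = ins[: e_len - best_t]
    return tsd, best_i - best_t, element


@dataclass(frozen=True)
class TSDLogo:
    """Position-frequency matrix of a TSD collection (rows A, C, G, T)."""

    counts: np.ndarray  # (4, L)
    consensus: str
    n_sequences: int

    BASES = "ACGT"


def build_tsd_logo(tsds: Iterable[str]) -> TSDLogo:
    """Position-frequency logo of TSD sequences of the modal length.

    Sequences whose length differs from the most common length are excluded
    (mirroring a consensus built only from the typical 5-nt duplications).
    Consensus letters are the column-maximizing base, with IUPAC ambiguity
    codes on ties.
    """
    seqs = [s.upper() for s in tsds if s]
    if not seqs:
        raise ValueError("need at least one non-empty TSD sequence")
    lengths = Counter(len(s) for s in seqs)
    modal_len = max(lengths.items(), key=lambda kv: (kv[1], kv[0]))[0]
    kept = [s for s in seqs if len(s) == modal_len]
    counts = np.zeros((4, modal_len), dtype=int)
    for s in kept:
        for j, base in enumerate(s):
            counts[TSDLogo.BASES.index(base), j] += 1
    consensus = []
    for j in range(modal_len):
        col = counts[:, j]
        winners = frozenset(TSDLogo.BASES[i] for i in range(4) if col[i] == col.max())
        consensus.append(_IUPAC[winners])
    return TSDLogo(counts, "".join(consensus), len(kept))


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifMatrix:
    """Log-odds weight matrix with relative-score scaling.

    Built from a position frequency (count) matrix with a pseudocount of
    0.01 x background added per cell; the relative score of a window maps the
    best attainable log-odds sum to 1 and the worst to 0.
    """

    name: str
    weights: np.ndarray  # (4, L) log-odds
    background: np.ndarray  # (4,)

    BASES = "ACGT"

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        name: str = "motif",
        background: Sequence[float] | None = None,
        pseudocount_scale: float = 0.01,
    ) -> "MotifMatrix":
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix (rows A,C,G,T)")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        bg = bg / bg.sum()
        pseudo = pseudocount_scale * bg[:, None] * counts.sum(axis=0, keepdims=True)
        freqs = (counts + pseudo) / (counts + pseudo).sum(axis=0, keepdims=True)
        weights = np.log2(freqs / bg[:, None])
        return cls(name, weights, bg)

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def score_max(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @property
    def score_min(self) -> float:
        return float(self.weights.min(axis=0).sum())

    def relative_score(self, window: str) -> float:
        lo, hi = self.score_min, self.score_max
        if hi == lo:
            raise ValueError("degenerate matrix: max and min scores coincide")
        s = 0.0
        for j, base in enumerate(window.upper()):
            i = self.BASES.find(base)
            if i < 0:  # ambiguous base scores as background (log-odds 0)
                continue
            s += self.weights[i, j]
        return (s - lo) / (hi - lo)


def scan_pwm(
    seq: str,
    m: MotifMatrix,
    threshold: float = 0.995,
    both_strands: bool = True,
) -> list[tuple[int, str, float]]:
    """Scan a sequence for PWM hits strictly above a relative-score threshold.

    Returns (position, strand, relative_score) tuples; positions are 0-based
    starts on the forward sequence for both strands. The reverse strand is
    scanned on the reverse complement, as needed for elements inserted in
    reverse orientation.
    """
    seq = seq.upper()
    L = m.length
    if len(seq) < L:
        raise ValueError("sequence shorter than the motif")
    hits = []
    for i in range(len(seq) - L + 1):
        rs = m.relative_score(seq[i : i + L])
        if rs > threshold:
            hits.append((i, "+", rs))
    if both_strands:
        rc = reverse_complement(seq)
        for i in range(len(rc) - L + 1):
            rs = m.relative_score(rc[i : i + L])
            if rs > threshold:
                hits.append((len(seq) - L - i, "-", rs))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def motif_spacing_change(
    motif_positions: Sequence[int],
    rec: InsertionRecord,
    insertion_point: int,
) -> dict[tuple[int, int], int]:
    """Spacing change per motif pair caused by one insertion.

    An insertion falling strictly between two motifs stretches their spacing
    by element_length + |TSD| (one extra TSD copy is created); pairs not
    spanning the insertion point are unchanged.
    """
    positions = list(motif_positions)
    if positions != sorted(positions):
        raise ValueError("motif positions must be sorted")
    delta = rec.element_length + len(rec.tsd)
    out = {}
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            spans = positions[i] < insertion_point < positions[j]
            out[(positions[i], positions[j])] = delta if spans else 0
    return out


# ---------------------------------------------------------------------------
# In-silico PCR genotyping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmpliconModel:
    """Band-size model of the three-primer presence/absence assay.

    FL and R flank the insertion site; L sits inside the element near its
    3' end in forward orientation. The printed reference sizes are: FL-R
    638 bp without the element, 638 + 428 = 1066 bp with it, and L-R 616 bp
    with a forward element at the reference position. Element size is added
    without the 5-bp TSD by default, matching 1066 = 638 + 428.
    """

    fl_r_absent: int = 638
    l_r_present_reference: int = 616
    element_length: int = 428
    include_tsd_in_band: bool = False
    tolerance: int = 20  # gel resolution, bp

    def __post_init__(self):
        if min(self.fl_r_absent, self.l_r_present_reference, self.element_length) <= 0:
            raise ValueError("amplicon sizes must be positive")

    @property
    def fl_r_present(self) -> int:
        return self.fl_r_absent + self.element_length


def predict_pcr_bands(
    rec: InsertionRecord | None,
    model: AmpliconModel = AmpliconModel(),
) -> dict:
    """Predict band sizes and the qualitative genotyping class for one allele.

    * no element -> FL-R at the absent size only;
    * forward element -> FL-R grows by the element (plus any flank
      duplication and, optionally, the TSD); L-R shifts by -offset since the
      L primer travels with the element while R stays on the genome;
    * reverse element -> the L primer points the wrong way, so no L-R product
      ("only FL-R" class).

    Classes mirror the genotyping table: present / absent / larger or smaller
    FL-R / larger or smaller L-R / only FL-R, judged against the reference
    sizes with the model's gel tolerance.
    """
    if rec is None:
        return {"bands": {"FL-R": model.fl_r_absent}, "class": "absent"}
    extra = len(rec.tsd) if model.include_tsd_in_band else 0
    fl_r = model.fl_r_present + rec.extras_flank_dup_bp + extra
    bands = {"FL-R": fl_r}
    if rec.orientation == "reverse":
        label = "only FL-R"
    else:
        l_r = model.l_r_present_reference - rec.offset_bp + extra
        if l_r <= 0:
            raise ValueError("impossible amplicon geometry: non-positive L-R size")
        bands["L-R"] = l_r
        tol = model.tolerance
        d_flr = fl_r - model.fl_r_present
        d_lr = l_r - model.l_r_present_reference
        if abs(d_flr) <= tol and abs(d_lr) <= tol:
            label = "present"
        elif abs(d_flr) > tol:
            label = "larger FL-R" if d_flr > 0 else "smaller FL-R"
        else:
            label = "larger L-R" if d_lr > 0 else "smaller L-R"
    return {"bands": bands, "class": label}


def classify_genotype(
    observed_bands: Iterable[float],
    model: AmpliconModel = AmpliconModel(),
    tolerance: float | None = None,
) -> str:
    """Classify an observed band-size set as present/absent/heterozygous.

    Bands are matched (within the gel tolerance) against the absent FL-R
    signature and the present FL-R / L-R signatures; mixtures of both allele
    signatures are heterozygous, anything else is "unexpected".
    """
    tol = model.tolerance if tolerance is None else tolerance
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    has_absent = has_present = has_unknown = False
    for b in observed_bands:
        if abs(b - model.fl_r_absent) <= tol:
            has_absent = True
        elif abs(b - model.fl_r_present) <= tol or abs(b - model.l_r_present_reference) <= tol:
            has_present = True
        else:
            has_unknown = True
    if has_unknown or not (has_absent or has_present):
        return "unexpected"
    if has_absent and has_present:
        return "heterozygous"
    return "present" if has_present else "absent"


# ---------------------------------------------------------------------------
# Alternative-TSS transcript arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """5'-UTR lengths of the two transcript isoforms at the reference allele.

    The TE-initiated transcript has a 276-bp 5'-UTR whose first 50 bp lie
    inside the element; a downstream TSS yields a 201-bp 5'-UTR independent
    of the insertion.
    """

    te_tss_utr_bp: int = 276
    te_contributed_bp: int = 50
    downstream_tss_utr_bp: int = 201

    def __post_init__(self):
        if self.te_contributed_bp > self.te_tss_utr_bp:
            raise ValueError("TE-contributed UTR cannot exceed the full UTR")


def transcript_utr_lengths(
    rec: InsertionRecord,
    ref_model: TranscriptModel = TranscriptModel(),
) -> dict:
    """5'-UTR lengths of the transcripts produced with a given insertion.

    The short (downstream-TSS) transcript always exists. A TE-initiated
    transcript exists only where the element seeds an internal TSS
    (``rec.te_internal_tss``: forward-oriented, gene-proximal elements); its
    UTR shrinks by the element's downstream offset — an element 7 bp closer
    to the gene yields a transcript 7 bp shorter.
    """
    out = {"downstream_tss_utr_bp": ref_model.downstream_tss_utr_bp}
    if rec.te_internal_tss:
        if rec.orientation == "reverse":
            raise ValueError("a reverse-oriented element cannot seed the TE TSS")
        utr = ref_model.te_tss_utr_bp - rec.offset_bp
        if utr <= 0:
            raise ValueError("offset places the TE TSS past the start codon")
        out["te_tss_utr_bp"] = utr
        out["te_contributed_bp"] = ref_model.te_contributed_bp
    return out


# ---------------------------------------------------------------------------
# Promoter-proximity classification
# ---------------------------------------------------------------------------

def _intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def promoter_5prime_fraction(
    te_intervals: Sequence[tuple[int, int]],
    gene_models: Sequence[dict],
    upstream_bp: int = 1000,
) -> tuple[int, int, float]:
    """Fraction of TE insertions in promoter / 5' gene regions.

    A TE (0-based half-open interval) qualifies if it overlaps the
    strand-aware ``upstream_bp`` window upstream of any gene's 5' end or
    overlaps the gene's 5'-most position itself. Gene models are dicts with
    ``start``, ``end`` (half-open) and ``strand`` ('+'/'-'). Returns
    (qualifying count, total, percentage rounded to one decimal).
    """
    qualifying = 0
    for te_start, te_end in te_intervals:
        if te_end <= te_start:
            raise ValueError("TE intervals must be non-empty half-open")
        ok = False
        for gene in gene_models:
            g_start, g_end, strand = gene["start"], gene["end"], gene["strand"]
            if strand == "+":
                win = (g_start - upstream_bp, g_start)
                five_prime = (g_start, g_start + 1)
            elif strand == "-":
                win = (g_end, g_end + upstream_bp)
                five_prime = (g_end - 1, g_end)
            else:
                raise ValueError(f"bad strand {strand!r}")
            if _intervals_overlap(te_start, te_end, *win) or _intervals_overlap(
                te_start, te_end, *five_prime
            ):
                ok = True
                break
        if ok:
            qualifying += 1
    total = len(te_intervals)
    pct = round(100.0 * qualifying / total, 1) if total else 0.0
    return qualifying, total, pct
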