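"""Methylation sensitivity of TF-DNA binding from paired DAP/ampDAP counts.

DAP-seq probes transcription-factor binding on native genomic DNA (cytosine
methylation preserved); ampDAP-seq uses the same library after PCR
amplification, which erases methylation.  The per-region log10 ratio of
normalized DAP to ampDAP coverage therefore isolates the effect of
methylation on binding: ratios below zero indicate repression on the native
(methylated) template.

This module provides the full analysis chain: normalized log-ratios, PWM
construction and best-site scanning, region-level methylation density,
methylated-cytosine counts within the best binding site, and per-motif-
position Pearson correlation between methylation probability and the
log-ratio, with Benjamini-Hochberg FDR control and masking of positions
with too few cytosines.

Coordinates are 0-based half-open (BED convention) throughout.  The W-box
core motif is handled in its displayed orientation G1 G2 T3 C4 A5 A6 (the
reverse complement of TTGACC), so "position 4" is a forward-strand cytosine
and positions 1 and 2 carry cytosines on the reverse strand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "PWM",
    "TFBSHit",
    "BoundRegion",
    "MethylationTrack",
    "log_ratio",
    "build_pwm",
    "read_meme_pwm",
    "write_meme_pwm",
    "scan_best_site",
    "methylation_density",
    "count_methylated_tfbs",
    "per_position_correlation",
    "bh_adjust",
    "mask_positions",
    "RunConfig",
    "run_methylation_sensitivity",
]

_ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# log-ratio
# ---------------------------------------------------------------------------

def log_ratio(
    dap_count: float,
    ampdap_count: float,
    dap_libsize: float,
    ampdap_libsize: float,
    pseudocount: float = 1.0,
) -> float:
    """log10 of library-size-normalized DAP coverage over ampDAP coverage.

    A pseudocount (default one read) is added to both counts before
    normalization so the ratio is always finite.  The function is
    antisymmetric under swapping the two experiments.
    """
    if dap_libsize <= 0 or ampdap_libsize <= 0:
        raise ValueError("library sizes must be positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    num = (dap_count + pseudocount) / dap_libsize
    den = (ampdap_count + pseudocount) / ampdap_libsize
    return math.log10(num / den)


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PWM:
    """Position weight matrix over ACGT with log-odds scoring.

    ``probs`` holds per-position base probabilities on the forward strand,
    shape (L, 4) in A, C, G, T order.  ``background`` is the base
    composition the log-odds are computed against.
    """

    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must have shape (L, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if bg.shape != (4,) or not np.all(bg > 0):
            raise ValueError("background must be 4 positive frequencies")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.probs.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """(L, 4) matrix of log2(p / background); -inf where p == 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background)

    def score(self, site: str) -> float:
        """Log-odds score of one site in PWM orientation; N contributes 0."""
        if len(site) != self.length:
            raise ValueError("site length must equal PWM length")
        lo = self.log_odds()
        total = 0.0
        for i, base in enumerate(site.upper()):
            if base == "N":
                continue
            total += lo[i, _CODE[base]]
        return total


def build_pwm(
    aligned_sites: Sequence[str],
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
) -> PWM:
    """Build a PWM from equal-length aligned binding sites.

    Column probabilities are (count + pseudocount/4) / (n + pseudocount),
    i.e. the pseudocount is split uniformly over the four bases.
    """
    if not aligned_sites:
        raise ValueError("need at least one site")
    sites = [s.upper() for s in aligned_sites]
    length = len(sites[0])
    if length == 0 or any(len(s) != length for s in sites):
        raise ValueError("sites must be non-empty and of equal length")
    counts = np.zeros((length, 4))
    for s in sites:
        for i, base in enumerate(s):
            if base not in _CODE:
                raise ValueError(f"non-ACGT character {base!r} in site {s!r}")
            counts[i, _CODE[base]] += 1
    n = len(sites)
    probs = (counts + pseudocount / 4.0) / (n + pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(probs=probs, background=bg, pseudocount=pseudocount)


def write_meme_pwm(pwm: PWM, name: str = "MOTIF1") -> str:
    """Serialize a PWM as MEME minimal-format text."""
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "Background letter frequencies",
        "A {:.6f} C {:.6f} G {:.6f} T {:.6f}".format(*pwm.background),
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {pwm.length} nsites= 20 E= 0",
    ]
    for row in pwm.probs:
        lines.append(" ".join(f"{p:.6f}" for p in row))
    return "\n".join(lines) + "\n"


def read_meme_pwm(text: str) -> PWM:
    """Parse the first motif of a MEME minimal-format file."""
    lines = text.splitlines()
    background = np.full(4, 0.25)
    i = 0
    rows: list[list[float]] = []
    width = None
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            fields = lines[i + 1].split()
            background = np.array([float(fields[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("letter-probability matrix"):
            tokens = line.replace("=", " = ").split()
            if "w" in tokens:
                width = int(tokens[tokens.index("w") + 2])
            i += 1
            while i < len(lines):
                vals = lines[i].split()
                if len(vals) != 4:
                    break
                try:
                    rows.append([float(v) for v in vals])
                except ValueError:
                    break
                i += 1
            break
        i += 1
    if not rows or (width is not None and len(rows) != width):
        raise ValueError("no letter-probability matrix block found")
    probs = np.array(rows)
    # renormalize: MEME files round to few decimals
    probs = probs / probs.sum(axis=1, keepdims=True)
    return PWM(probs=probs, background=background)


# ---------------------------------------------------------------------------
# best-site scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TFBSHit:
    """Best PWM window within one bound region.

    ``offset`` is 0-based from the region start on the forward strand;
    ``site`` is given in PWM orientation (reverse-complemented for minus-
    strand hits).
    """

    region_id: str
    offset: int
    strand: str
    score: float
    site: str


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int64)  # 4 = N / unknown
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    return codes


def scan_best_site(sequence: str, pwm: PWM, region_id: str = "") -> TFBSHit:
    """Best log-odds window over both strands of ``sequence``.

    Ties are broken toward the smaller forward-strand offset, then toward
    the forward strand.  N bases contribute a log-odds of 0 (background).
    """
    seq = sequence.upper()
    n, L = len(seq), pwm.length
    if n < L:
        raise ValueError("sequence shorter than PWM")
    lo = np.nan_to_num(pwm.log_odds(), neginf=-1e9)
    lo5 = np.hstack([lo, np.zeros((L, 1))])  # column 4: N scores 0

    codes = _encode(seq)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    pos_idx = np.arange(L)
    scores_fwd = lo5[pos_idx, win].sum(axis=1)

    rc_codes = _encode(revcomp(seq))
    rc_win = np.lib.stride_tricks.sliding_window_view(rc_codes, L)
    scores_rc = lo5[pos_idx, rc_win].sum(axis=1)
    # rc window starting at index i covers forward offset n - L - i
    scores_rev = scores_rc[::-1]

    best = max(scores_fwd.max(), scores_rev.max())
    tol = 1e-12 * max(1.0, abs(best))
    for offset in range(n - L + 1):
        if scores_fwd[offset] >= best - tol:
            return TFBSHit(region_id, offset, "+", float(scores_fwd[offset]),
                           seq[offset:offset + L])
        if scores_rev[offset] >= best - tol:
            return TFBSHit(region_id, offset, "-", float(scores_rev[offset]),
                           revcomp(seq[offset:offset + L]))
    raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# regions and methylation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundRegion:
    """A TF-bound genomic region with DAP and ampDAP read counts."""

    region_id: str
    chrom: str
    start: int
    end: int
    dap_count: float
    ampdap_count: float
    dap_libsize: float
    ampdap_libsize: float
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.dap_count < 0 or self.ampdap_count < 0:
            raise ValueError("counts must be non-negative")
        if self.dap_libsize <= 0 or self.ampdap_libsize <= 0:
            raise ValueError("library sizes must be positive")

    @property
    def log_ratio(self) -> float:
        return log_ratio(self.dap_count, self.ampdap_count,
                         self.dap_libsize, self.ampdap_libsize,
                         self.pseudocount)

    def sequence(self, genome: Mapping[str, str]) -> str:
        seq = genome[self.chrom]
        if self.end > len(seq):
            raise ValueError(
                f"region {self.region_id} extends past end of {self.chrom}")
        return seq[self.start:self.end].upper()


class MethylationTrack:
    """Per-cytosine methylation probabilities with strand and context.

    Each record is (chrom, 0-based position, strand, context in
    {CG, CHG, CHH}, probability in [0, 1]); at most one record per
    (chrom, position, strand).  Positions of minus-strand cytosines are
    given in forward coordinates (the position of the G on the forward
    strand).  Missing cytosines are treated as unmethylated (probability 0).
    """

    CONTEXTS = frozenset({"CG", "CHG", "CHH"})

    def __init__(self, records: Iterable[tuple[str, int, str, str, float]]):
        self._probs: dict[tuple[str, int, str], float] = {}
        self._contexts: dict[tuple[str, int, str], str] = {}
        for chrom, pos, strand, context, prob in records:
            if strand not in ("+", "-"):
                raise ValueError(f"bad strand {strand!r}")
            if context not in self.CONTEXTS:
                raise ValueError(f"bad context {context!r}")
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"probability {prob} outside [0, 1]")
            key = (chrom, int(pos), strand)
            if key in self._probs:
                raise ValueError(f"duplicate methylation record at {key}")
            self._probs[key] = float(prob)
            self._contexts[key] = context

    def __len__(self) -> int:
        return len(self._probs)

    def probability(self, chrom: str, pos: int, strand: str) -> float:
        """Methylation probability; 0.0 for cytosines with no record."""
        return self._probs.get((chrom, pos, strand), 0.0)

    def context(self, chrom: str, pos: int, strand: str) -> str | None:
        return self._contexts.get((chrom, pos, strand))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MethylationTrack":
        cols = ["chrom", "position", "strand", "context", "probability"]
        return cls(frame[cols].itertuples(index=False, name=None))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, p, s, self._contexts[(c, p, s)], prob)
            for (c, p, s), prob in sorted(self._probs.items())
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "position", "strand", "context",
                           "probability"])


def _cytosine_positions(seq: str, start: int) -> list[tuple[int, str]]:
    """(forward position, strand) of every cytosine in seq on either strand."""
    out = []
    for i, base in enumerate(seq):
        if base == "C":
            out.append((start + i, "+"))
        elif base == "G":
            out.append((start + i, "-"))
    return out


def methylation_density(
    region: BoundRegion,
    genome: Mapping[str, str],
    track: MethylationTrack,
    threshold: float = 0.5,
) -> float:
    """Proportion of region cytosines with methylation probability > threshold.

    Cytosines on both strands count; the inequality is strict, so
    probability exactly equal to the threshold does not count as
    methylated.  A region with no cytosines yields 0.0 with a warning.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    positions = _cytosine_positions(region.sequence(genome), region.start)
    if not positions:
        warnings.warn(
            f"region {region.region_id} contains no cytosines; density set to 0",
            stacklevel=2)
        return 0.0
    n_meth = sum(
        1 for pos, strand in positions
        if track.probability(region.chrom, pos, strand) > threshold)
    return n_meth / len(positions)


def methylated_cytosine_number(
    region: BoundRegion,
    genome: Mapping[str, str],
    track: MethylationTrack,
    threshold: float = 0.5,
) -> int:
    """Absolute count of methylated cytosines in a bound region.

    Companion to :func:`methylation_density` for workflows that report the
    raw number rather than the proportion.
    """
    positions = _cytosine_positions(region.sequence(genome), region.start)
    return sum(
        1 for pos, strand in positions
        if track.probability(region.chrom, pos, strand) > threshold)


def count_methylated_tfbs(
    hit: TFBSHit,
    region: BoundRegion,
    genome: Mapping[str, str],
    track: MethylationTrack,
    threshold: float = 0.5,
) -> int:
    """Number of methylated cytosines (both strands) within the best site.

    A cytosine is methylated when its track probability strictly exceeds
    ``threshold``; cytosines without a record count as unmethylated.
    """
    L = len(hit.site)
    if hit.offset < 0 or region.start + hit.offset + L > region.end:
        raise ValueError("hit lies outside its region")
    site_start = region.start + hit.offset
    seq = region.sequence(genome)[hit.offset:hit.offset + L]
    return sum(
        1 for pos, strand in _cytosine_positions(seq, site_start)
        if track.probability(region.chrom, pos, strand) > threshold)


# ---------------------------------------------------------------------------
# per-position correlation with FDR masking
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Standard step-up with monotonicity enforcement: q_(i) =
    min_{j >= i} p_(j) * m / j, clipped to 1.  Order-preserving and
    elementwise >= p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _site_genomic_map(hit: TFBSHit, region: BoundRegion) -> list[tuple[int, str]]:
    """For motif positions 1..L and motif strand '+', the genomic
    (position, strand) each maps to; motif strand '-' is the opposite."""
    L = len(hit.site)
    start = region.start + hit.offset
    if hit.strand == "+":
        return [(start + j, "+") for j in range(L)]
    return [(start + L - 1 - j, "-") for j in range(L)]


STATUS_TESTED = "tested"
STATUS_BLANK_FDR = "blank_fdr"
STATUS_INSUFFICIENT = "insufficient_n"
STATUS_ZERO_VARIANCE = "zero_variance"


def per_position_correlation(
    hits: Sequence[TFBSHit],
    regions: Sequence[BoundRegion],
    genome: Mapping[str, str],
    track: MethylationTrack,
    min_pairs: int = 3,
    min_n: int = 10,
    fdr: float = 0.05,
    include_pooled: bool = True,
) -> pd.DataFrame:
    """Per-motif-position Pearson correlation of methylation with binding.

    For each motif position (1..L) and strand, regions whose best-site base
    at that position is a cytosine contribute a pair (log10 DAP/ampDAP
    ratio, methylation probability).  Cytosines without a methylome record
    contribute probability 0.  Position indices always refer to the motif:
    for minus-strand hits the genomic coordinates and strands are
    translated so that, e.g., motif position 4 on the motif forward strand
    denotes the same base-pair contact regardless of the hit orientation.

    Returns a PositionEffectTable: one row per (position, strand) with
    Pearson r, two-sided p, BH-adjusted q, n_cytosines, and a masking
    status.  With ``include_pooled`` both strands at a position are also
    pooled into rows with strand 'both' (their own BH family).  Fewer than
    ``min_pairs`` usable pairs, or zero variance in either variable, is
    reported via the status column, never raised.
    """
    if len(hits) != len(regions):
        raise ValueError("hits and regions must correspond one-to-one")
    if len(regions) < 3:
        raise ValueError("need at least 3 regions")
    L = len(hits[0].site)
    by_id = {r.region_id: r for r in regions}

    pairs: dict[tuple[int, str], list[tuple[float, float]]] = {
        (j, s): [] for j in range(1, L + 1) for s in "+-"}
    for hit in hits:
        region = by_id[hit.region_id]
        ratio = region.log_ratio
        gmap = _site_genomic_map(hit, region)
        site = hit.site
        for j in range(L):
            gpos, gstrand = gmap[j]
            if site[j] == "C":  # cytosine on the motif forward strand
                prob = track.probability(region.chrom, gpos, gstrand)
                pairs[(j + 1, "+")].append((ratio, prob))
            elif site[j] == "G":  # cytosine on the motif reverse strand
                opp = "-" if gstrand == "+" else "+"
                prob = track.probability(region.chrom, gpos, opp)
                pairs[(j + 1, "-")].append((ratio, prob))

    rows = []

    def _row(position: int, strand: str, data: list[tuple[float, float]]):
        n = len(data)
        r = p = np.nan
        status = STATUS_INSUFFICIENT
        if n >= min_pairs:
            x = np.array([d[0] for d in data])
            y = np.array([d[1] for d in data])
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                status = STATUS_ZERO_VARIANCE
            else:
                r, p = stats.pearsonr(x, y)
                status = STATUS_TESTED
        rows.append({"position": position, "strand": strand, "r": r,
                     "p": p, "q": np.nan, "n_cytosines": n,
                     "status": status})

    for j in range(1, L + 1):
        for s in "+-":
            _row(j, s, pairs[(j, s)])
    if include_pooled:
        for j in range(1, L + 1):
            _row(j, "both", pairs[(j, "+")] + pairs[(j, "-")])

    table = pd.DataFrame(rows)
    # BH families: the per-strand tests for one TF form one family; pooled
    # rows are adjusted separately so they do not dilute the primary family.
    for family in (table["strand"] != "both", table["strand"] == "both"):
        sel = family & table["p"].notna()
        if sel.any():
            table.loc[sel, "q"] = bh_adjust(table.loc[sel, "p"].to_numpy())
    return mask_positions(table, min_n=min_n, fdr=fdr)


def mask_positions(
    table: pd.DataFrame,
    min_n: int = 10,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Apply the heatmap masking rules to a PositionEffectTable.

    Positions with fewer than ``min_n`` cytosines are flagged
    ``insufficient_n`` regardless of significance; tested positions whose
    BH-adjusted q exceeds ``fdr`` are blanked (``blank_fdr``).  r, p and q
    values are never altered, only the status column.
    """
    out = table.copy()
    for idx, row in out.iterrows():
        if row["n_cytosines"] < min_n:
            out.at[idx, "status"] = STATUS_INSUFFICIENT
        elif not np.isfinite(row["r"]):
            out.at[idx, "status"] = STATUS_ZERO_VARIANCE
        elif row["q"] > fdr:
            out.at[idx, "status"] = STATUS_BLANK_FDR
        else:
            out.at[idx, "status"] = STATUS_TESTED
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths and thresholds for one methylation-sensitivity run."""

    peaks: str | Path
    genome: str | Path
    counts: str | Path
    methylome: str | Path
    pwm: str | Path
    out_dir: str | Path
    min_n: int = 10
    fdr: float = 0.05
    pseudocount: float = 1.0
    density_threshold: float = 0.5
    make_plots: bool = False


@dataclass
class RunResult:
    """Tables produced by :func:`run_methylation_sensitivity`."""

    regions: pd.DataFrame          # per-region density / ratio / best hit
    count_bins: pd.DataFrame       # ratio distribution per methylated-C count
    position_effects: pd.DataFrame # masked PositionEffectTable
    scatter: pd.DataFrame          # per-position (probability, ratio) pairs


def run_methylation_sensitivity(config: RunConfig) -> RunResult:
    """Run the full DAP/ampDAP methylation-sensitivity analysis.

    Reads peaks (BED), genome (FASTA), per-region counts (TSV), a
    methylation track (TSV) and a PWM (MEME minimal text); writes TSV
    report tables plus a YAML run log into ``config.out_dir`` and returns
    the tables.
    """
    from . import io as msio

    peaks = msio.read_bed(config.peaks)
    if peaks.empty:
        raise ValueError(f"empty peak file: {config.peaks}")
    genome = msio.read_fasta(config.genome)
    counts = pd.read_csv(config.counts, sep="\t")
    track = MethylationTrack.from_frame(pd.read_csv(config.methylome, sep="\t"))
    pwm = read_meme_pwm(Path(config.pwm).read_text())

    merged = peaks.merge(counts, on="region_id", how="left")
    if merged["dap_count"].isna().any():
        missing = merged.loc[merged["dap_count"].isna(), "region_id"].tolist()
        raise ValueError(
            f"region ids missing from counts table: {missing[:5]}")

    regions, hits, rows = [], [], []
    for rec in merged.itertuples(index=False):
        region = BoundRegion(
            region_id=rec.region_id, chrom=rec.chrom,
            start=int(rec.start), end=int(rec.end),
            dap_count=float(rec.dap_count),
            ampdap_count=float(rec.ampdap_count),
            dap_libsize=float(rec.dap_libsize),
            ampdap_libsize=float(rec.ampdap_libsize),
            pseudocount=config.pseudocount)
        hit = scan_best_site(region.sequence(genome), pwm, region.region_id)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            density = methylation_density(
                region, genome, track, config.density_threshold)
        n_meth = count_methylated_tfbs(
            hit, region, genome, track, config.density_threshold)
        regions.append(region)
        hits.append(hit)
        rows.append({
            "region_id": region.region_id, "chrom": region.chrom,
            "start": region.start, "end": region.end,
            "log_ratio": region.log_ratio,
            "methylation_density": density,
            "n_methylated_tfbs": n_meth,
            "site_offset": hit.offset, "site_strand": hit.strand,
            "site_score": hit.score, "site": hit.site})

    region_table = pd.DataFrame(rows)
    count_bins = (
        region_table.groupby("n_methylated_tfbs")["log_ratio"]
        .agg(["count", "mean", "median", "std"]).reset_index())
    effects = per_position_correlation(
        hits, regions, genome, track,
        min_n=config.min_n, fdr=config.fdr)

    scatter_rows = []
    by_id = {r.region_id: r for r in regions}
    for hit in hits:
        region = by_id[hit.region_id]
        gmap = _site_genomic_map(hit, region)
        for j, base in enumerate(hit.site):
            if base not in "CG":
                continue
            gpos, gstrand = gmap[j]
            strand = "+" if base == "C" else "-"
            qpos_strand = gstrand if base == "C" else (
                "-" if gstrand == "+" else "+")
            scatter_rows.append({
                "region_id": region.region_id, "position": j + 1,
                "strand": strand,
                "probability": track.probability(
                    region.chrom, gpos, qpos_strand),
                "log_ratio": region.log_ratio})
    scatter = pd.DataFrame(scatter_rows)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    region_table.to_csv(out_dir / "regions.tsv", sep="\t", index=False)
    count_bins.to_csv(out_dir / "tfbs_count_bins.tsv", sep="\t", index=False)
    effects.to_csv(out_dir / "position_effects.tsv", sep="\t", index=False)
    scatter.to_csv(out_dir / "position_scatter.tsv", sep="\t", index=False)
    (out_dir / "run.yaml").write_text(yaml.safe_dump({
        "peaks": str(config.peaks), "genome": str(config.genome),
        "counts": str(config.counts), "methylome": str(config.methylome),
        "pwm": str(config.pwm), "min_n": config.min_n, "fdr": config.fdr,
        "pseudocount": config.pseudocount,
        "density_threshold": config.density_threshold,
        "n_regions": len(region_table),
        "missing_methylome_policy": "probability 0 (unmethylated)",
    }))

    if config.make_plots:
        _write_plots(region_table, effects, out_dir)

    return RunResult(region_table, count_bins, effects, scatter)


def _write_plots(region_table: pd.DataFrame, effects: pd.DataFrame,
                 out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(region_table["methylation_density"],
               region_table["log_ratio"], s=8, alpha=0.5)
    ax.set_xlabel("methylation density")
    ax.set_ylabel("log10 DAP/ampDAP")
    fig.savefig(out_dir / "density_vs_ratio.png", dpi=150)
    plt.close(fig)

    tested = effects[effects["strand"] != "both"]
    pivot = tested.pivot(index="strand", columns="position", values="r")
    fig, ax = plt.subplots(figsize=(6, 2.5))
    im = ax.imshow(pivot.to_numpy(), cmap="RdBu", vmin=-1, vmax=1,
                   aspect="auto")
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    ax.set_xticks(range(len(pivot.columns)), pivot.columns)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.savefig(out_dir / "position_effect_heatmap.png", dpi=150)
    plt.close(fig)
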