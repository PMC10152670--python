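"""Synthetic inputs for the whole pipeline: peak sets with planted
methylation effects, BLI sensorgrams from a ground-truth scenario
registry, and idealized base-pair/tyrosine geometry fixtures.

The generators define the study conditions the downstream analyses are
validated against, so every default here is a deliberate choice:

* The W-box core motif is stored in the displayed orientation
  G1 G2 T3 C4 A5 A6 (reverse complement of TTGACC).  Under this
  convention "C4" is a cytosine on the motif forward strand (CHH
  context) and positions 1 and 2 carry cytosines on the reverse strand.
* The planted generative model for the DAP/ampDAP log-ratio of region r is

      log10(DAP_r / ampDAP_r) = baseline - sum_pos beta_pos * m_pos + eps,

  with m_pos the methylation probability of the planted-site cytosine at
  that motif position and eps ~ Normal(0, noise_sd).  Methylation only
  represses binding, so effect sizes are non-negative.
* The BLI scenario registry anchors the measured affinities of the
  AtWRKY40 DNA-binding domain for the W-box duplex: 630 nM unmethylated,
  essentially unchanged for reverse-strand 5mC at positions 1 or 2,
  12 uM for forward-strand 5mC at position 4, and 9.2 uM (no additive
  effect) when all three cytosines are methylated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .bli_kinetics import PhaseSchedule, Sensorgram, simulate_sensorgram
from .dap_methyl import PWM, BoundRegion, MethylationTrack, build_pwm, revcomp
from .struct_contacts import Atom, StructureEnsemble, methylate_cytosine

__all__ = [
    "EffectVector",
    "ScenarioSpec",
    "SCENARIOS",
    "PeaksetBundle",
    "wbox_pwm",
    "generate_methylome_peakset",
    "default_concentration_ladder",
    "generate_sensorgram_set",
    "build_geometry_fixture",
]


# ---------------------------------------------------------------------------
# planted effect model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectVector:
    """Planted per-motif-position methylation effects on the log10 ratio.

    ``beta`` maps (1-based motif position, strand) to a non-negative
    effect in log10-ratio units per unit methylation probability; entries
    are only meaningful at positions whose motif consensus base is a
    cytosine on that strand.  ``baseline`` is the mean log10 ratio of a
    fully unmethylated site and ``noise_sd`` the Gaussian residual SD.
    """

    beta: dict = field(default_factory=dict)
    baseline: float = 0.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        for key, value in self.beta.items():
            pos, strand = key
            if strand not in ("+", "-") or pos < 1:
                raise ValueError(f"bad effect key {key}")
            if not np.isfinite(value) or value < 0:
                raise ValueError(
                    f"effect at {key} must be finite and >= 0, got {value}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def validate_against(self, pwm: PWM) -> None:
        """Effects may only sit on consensus cytosines of the motif."""
        consensus = pwm.consensus
        for pos, strand in self.beta:
            if pos > pwm.length:
                raise ValueError(f"effect position {pos} outside PWM")
            base = consensus[pos - 1]
            expected = "C" if strand == "+" else "G"
            if base != expected:
                raise ValueError(
                    f"no consensus cytosine at position {pos} strand {strand}")

    @classmethod
    def wbox_default(cls) -> "EffectVector":
        """Effect sizes mirroring the observed per-position ordering:
        strongest at C4 (forward), intermediate at C2, mild at C1 (both
        reverse strand)."""
        return cls(beta={(4, "+"): 0.6, (2, "-"): 0.45, (1, "-"): 0.25},
                   baseline=0.0, noise_sd=0.1)

    @classmethod
    def null(cls, noise_sd: float = 0.1) -> "EffectVector":
        return cls(beta={}, baseline=0.0, noise_sd=noise_sd)


def wbox_pwm() -> PWM:
    """A peaked W-box PWM with consensus GGTCAA (displayed orientation).

    Position 1 tolerates A (the W-box core is TTGAC(C/T), i.e. (A/G)GTCAA
    in this orientation); all other positions are strongly constrained.
    """
    sites = ["GGTCAA"] * 16 + ["AGTCAA"] * 3 + ["GGTCAT"]
    return build_pwm(sites, pseudocount=1.0)


# ---------------------------------------------------------------------------
# peakset generator
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _sample_site(rng: np.random.Generator, pwm: PWM) -> str:
    out = []
    for col in pwm.probs:
        out.append(_BASES[rng.choice(4, p=col / col.sum())])
    return "".join(out)


def _context(seq: str, i: int, strand: str) -> str:
    """Plant methylation context (CG/CHG/CHH) of the cytosine at forward
    position i; for '-' the cytosine pairs the G at i and reads leftward."""
    if strand == "+":
        nxt = seq[i + 1] if i + 1 < len(seq) else "N"
        nxt2 = seq[i + 2] if i + 2 < len(seq) else "N"
        if nxt == "G":
            return "CG"
        if nxt2 == "G":
            return "CHG"
        return "CHH"
    nxt = seq[i - 1] if i - 1 >= 0 else "N"
    nxt2 = seq[i - 2] if i - 2 >= 0 else "N"
    if nxt == "C":
        return "CG"
    if nxt2 == "C":
        return "CHG"
    return "CHH"


@dataclass
class PeaksetBundle:
    """All inputs for one synthetic DAP/ampDAP analysis run."""

    genome: dict
    peaks: pd.DataFrame
    methylation: pd.DataFrame
    counts: pd.DataFrame
    truth: pd.DataFrame
    pwm: PWM

    @property
    def track(self) -> MethylationTrack:
        return MethylationTrack.from_frame(self.methylation)

    def to_regions(self, pseudocount: float = 1.0) -> list[BoundRegion]:
        merged = self.peaks.merge(self.counts, on="region_id")
        return [
            BoundRegion(r.region_id, r.chrom, int(r.start), int(r.end),
                        float(r.dap_count), float(r.ampdap_count),
                        float(r.dap_libsize), float(r.ampdap_libsize),
                        pseudocount)
            for r in merged.itertuples(index=False)
        ]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        from .dap_methyl import write_meme_pwm

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "peaks": out / "peaks.bed",
            "methylome": out / "methylation.tsv",
            "counts": out / "counts.tsv",
            "pwm": out / "motif.meme",
            "truth": out / "truth.tsv",
        }
        msio.write_fasta(self.genome, paths["genome"])
        msio.write_bed(self.peaks, paths["peaks"])
        self.methylation.to_csv(paths["methylome"], sep="\t", index=False)
        self.counts.to_csv(paths["counts"], sep="\t", index=False)
        paths["pwm"].write_text(write_meme_pwm(self.pwm, "WBOX"))
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def generate_methylome_peakset(
    n_regions: int,
    pwm: PWM | None = None,
    effects: EffectVector | None = None,
    seed: int = 0,
    region_length: int = 200,
    spacer_length: int = 50,
    ampdap_mean: float = 200.0,
    libsize: float = 1.0e6,
    count_noise: bool = True,
) -> PeaksetBundle:
    """Simulate a genome, bound regions, methylome and DAP/ampDAP counts.

    Each region carries exactly one planted site sampled from the PWM
    (random orientation).  Planted-site cytosines draw their methylation
    probability from the bimodal mixture 0.5*Beta(0.5, 5) +
    0.5*Beta(5, 0.5), so both unmethylated and strongly methylated states
    are common; background cytosines draw from Beta(1, 10).  ampDAP
    counts follow a region-specific log-normal baseline; DAP counts
    realize log10(DAP/ampDAP) = baseline - sum beta*m + eps through
    scaling of the expected count.  With ``count_noise`` the expected
    counts are Poisson-realized (sequencing-like); without it they are
    kept exact so the planted predictor can be recovered to machine
    precision.  Output is reproducible bit-for-bit for a fixed seed.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    pwm = pwm or wbox_pwm()
    effects = effects or EffectVector.wbox_default()
    effects.validate_against(pwm)
    L = pwm.length
    if L < 6:
        raise ValueError("PWM must have length >= 6")
    if region_length < L + 20:
        raise ValueError("regions too short for the planted site")

    rng = np.random.default_rng(seed)
    chrom = "chr1"
    parts: list[str] = []
    cursor = 0
    peaks_rows, truth_rows = [], []
    site_spans: list[tuple[int, int]] = []

    for r in range(n_regions):
        parts.append(_random_seq(rng, spacer_length))
        cursor += spacer_length
        start = cursor
        site = _sample_site(rng, pwm)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = site if strand == "+" else revcomp(site)
        offset = int(rng.integers(10, region_length - L - 10))
        region_seq = (_random_seq(rng, offset) + planted
                      + _random_seq(rng, region_length - offset - L))
        parts.append(region_seq)
        cursor += region_length
        site_spans.append((start + offset, start + offset + L))
        peaks_rows.append({
            "chrom": chrom, "start": start, "end": start + region_length,
            "region_id": f"region_{r:05d}", "score": 0, "strand": "."})
        truth_rows.append({
            "region_id": f"region_{r:05d}", "site_offset": offset,
            "site_strand": strand, "site": site})
    parts.append(_random_seq(rng, spacer_length))
    genome_seq = "".join(parts)
    genome = {chrom: genome_seq}

    # methylation probabilities for every cytosine on either strand
    in_site = np.zeros(len(genome_seq), dtype=bool)
    for s, e in site_spans:
        in_site[s:e] = True
    meth_rows = []
    for i, base in enumerate(genome_seq):
        if base == "C":
            strand = "+"
        elif base == "G":
            strand = "-"
        else:
            continue
        if in_site[i]:
            if rng.random() < 0.5:
                prob = rng.beta(0.5, 5.0)
            else:
                prob = rng.beta(5.0, 0.5)
        else:
            prob = rng.beta(1.0, 10.0)
        meth_rows.append((chrom, i, strand, _context(genome_seq, i, strand),
                          float(prob)))
    methylation = pd.DataFrame(
        meth_rows,
        columns=["chrom", "position", "strand", "context", "probability"])
    prob_lookup = {(p, s): pr for _, p, s, _, pr in
                   methylation.itertuples(index=False, name=None)}

    # counts from the planted linear model
    counts_rows = []
    for r, (site_start, site_end) in enumerate(site_spans):
        tr = truth_rows[r]
        predictor = effects.baseline
        m_by_pos = {}
        for (pos, strand), beta in effects.beta.items():
            # map motif position -> genomic (position, strand)
            if tr["site_strand"] == "+":
                gpos = site_start + pos - 1
                gstrand = strand
            else:
                gpos = site_end - pos
                gstrand = "-" if strand == "+" else "+"
            base = genome_seq[gpos]
            has_c = (base == "C" and gstrand == "+") or (
                base == "G" and gstrand == "-")
            m = prob_lookup.get((gpos, gstrand), 0.0) if has_c else 0.0
            m_by_pos[(pos, strand)] = m
            predictor -= beta * m
        eps = rng.normal(0.0, effects.noise_sd) if effects.noise_sd > 0 else 0.0
        log_ratio_true = predictor + eps
        amp_mean = ampdap_mean * np.exp(rng.normal(0.0, 0.3))
        dap_mean = amp_mean * 10.0 ** log_ratio_true
        if count_noise:
            dap = int(rng.poisson(dap_mean))
            amp = int(rng.poisson(amp_mean))
        else:
            dap, amp = float(dap_mean), float(amp_mean)
        counts_rows.append({
            "region_id": tr["region_id"], "dap_count": dap,
            "ampdap_count": amp, "dap_libsize": libsize,
            "ampdap_libsize": libsize})
        tr["log_ratio_true"] = log_ratio_true
        for (pos, strand), m in m_by_pos.items():
            tr[f"m_{pos}{strand}"] = m

    return PeaksetBundle(
        genome=genome,
        peaks=pd.DataFrame(peaks_rows),
        methylation=methylation,
        counts=pd.DataFrame(counts_rows),
        truth=pd.DataFrame(truth_rows),
        pwm=pwm,
    )


# ---------------------------------------------------------------------------
# BLI scenario registry and sensorgram sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """Ground-truth 1:1 binding scenario for one duplex methylation state.

    ``K_D_nM`` anchors the measured steady-state affinity; ``k_on`` is
    derived as k_off / K_D so the kinetic identity holds exactly.
    """

    name: str
    K_D_nM: float
    k_off: float
    R_max: float = 1.0
    illustrative: bool = False

    def __post_init__(self) -> None:
        if self.K_D_nM <= 0 or self.k_off <= 0 or self.R_max <= 0:
            raise ValueError("scenario parameters must be positive")

    @property
    def K_D(self) -> float:
        """K_D in molar."""
        return self.K_D_nM * 1e-9

    @property
    def k_on(self) -> float:
        return self.k_off / self.K_D


SCENARIOS: dict[str, ScenarioSpec] = {
    # measured steady-state affinities of the AtWRKY40 DBD for the 16-mer
    # W-box duplex in each methylation state; k_off chosen so that
    # k_on = 2e5 /M/s for the unmethylated duplex
    "unmethylated": ScenarioSpec("unmethylated", 630.0, 0.126, R_max=1.2),
    "5mC1": ScenarioSpec("5mC1", 630.0, 0.126, R_max=1.2),
    "5mC2": ScenarioSpec("5mC2", 630.0, 0.126, R_max=1.2),
    "5mC4": ScenarioSpec("5mC4", 12000.0, 0.60, R_max=1.1),
    "5mC1+2+4": ScenarioSpec("5mC1+2+4", 9200.0, 0.55, R_max=1.1),
    # illustrative stand-in: binding loss comparable to, and slightly
    # stronger than, 5mC4 — not a measured affinity
    "C4T_mutant": ScenarioSpec("C4T_mutant", 20000.0, 0.80, R_max=1.0,
                               illustrative=True),
}

# representative 16-mer duplex containing the W-box core in the displayed
# orientation (synthetic stand-in for the promoter fragment used on the
# sensor; the core GGTCAA spans duplex positions 6-11)
WBOX_DUPLEX_16MER = "TCAATGGTCAATCGAT"


def default_concentration_ladder(scenario: ScenarioSpec) -> list[float]:
    """Five analyte concentrations (molar) spanning 0.2-5x K_D."""
    return [scenario.K_D * f for f in (0.2, 0.5, 1.0, 2.0, 5.0)]


def generate_sensorgram_set(
    scenario: ScenarioSpec,
    concentrations: list[float] | None = None,
    schedule: PhaseSchedule | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[Sensorgram]:
    """Simulate the five-concentration sensorgram set for one scenario.

    Concentrations are molar; the default ladder spans 0.2-5x the
    scenario K_D.  Responses follow the 1:1 model plus i.i.d. Gaussian
    noise of SD ``noise_sd`` (response units, nm).
    """
    if concentrations is None:
        concentrations = default_concentration_ladder(scenario)
    if not concentrations:
        raise ValueError("concentration list must not be empty")
    if len(set(concentrations)) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    if any(c <= 0 for c in concentrations):
        raise ValueError("concentrations must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    schedule = schedule or PhaseSchedule()
    rng = np.random.default_rng(seed)
    return [
        simulate_sensorgram(C, scenario.k_on, scenario.k_off, scenario.R_max,
                            schedule=schedule, noise_sd=noise_sd, rng=rng)
        for C in sorted(concentrations)
    ]


# ---------------------------------------------------------------------------
# geometry fixture
# ---------------------------------------------------------------------------

# standard base-frame in-plane coordinates (A) of the ring and exocyclic
# heavy atoms; the paired guanine is the same frame mirrored through y=0
_CYTOSINE_XY = {
    "N1": (-1.285, 4.542), "C2": (-1.472, 3.158), "O2": (-2.628, 2.709),
    "N3": (-0.391, 2.344), "C4": (0.837, 2.868), "N4": (1.875, 2.027),
    "C5": (1.056, 4.275), "C6": (-0.023, 5.068),
}
_GUANINE_XY = {
    "N9": (-1.289, 4.551), "C8": (0.023, 4.962), "N7": (0.870, 3.969),
    "C5": (0.071, 2.833), "C6": (0.424, 1.460), "O6": (1.554, 0.955),
    "N1": (-0.700, 0.641), "C2": (-1.999, 1.087), "N2": (-2.949, 0.139),
    "N3": (-2.342, 2.364), "C4": (-1.265, 3.177),
}
_RING_BOND = 1.39       # aromatic C-C, A
_CZ_OH_BOND = 1.36      # phenol C-O, A
_CONTACT_SETUP = 2 * 1.70 + 0.2  # C...C at vdW sum plus 0.2 A


def _tyrosine_fragment(c4: np.ndarray, c5: np.ndarray,
                       c6: np.ndarray) -> dict[str, np.ndarray]:
    """Phenol ring placed so its nearest carbon (CE1) sits at van der
    Waals contact distance from the cytosine C5 along the external
    bisector of the C4-C5-C6 angle — exactly where a C5-methyl group
    would point."""
    v4 = (c4 - c5) / np.linalg.norm(c4 - c5)
    v6 = (c6 - c5) / np.linalg.norm(c6 - c5)
    u = -(v4 + v6)
    u /= np.linalg.norm(u)
    normal = np.cross(v4, v6)
    normal /= np.linalg.norm(normal)
    v = np.cross(normal, u)  # in-plane, perpendicular to u
    center = c5 + (_CONTACT_SETUP + _RING_BOND) * u
    angles = {"CD2": 0.0, "CG": 60.0, "CD1": 120.0, "CE1": 180.0,
              "CZ": 240.0, "CE2": 300.0}
    atoms = {}
    for name, deg in angles.items():
        rad = np.deg2rad(deg)
        atoms[name] = center + _RING_BOND * (np.cos(rad) * u + np.sin(rad) * v)
    oh_dir = (atoms["CZ"] - center) / _RING_BOND
    atoms["OH"] = atoms["CZ"] + _CZ_OH_BOND * oh_dir
    return atoms


def _rigid_transform(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-model rotation + translation (distance-preserving)."""
    a, b = 0.23 * k, 0.11 * k
    ca, sa, cb, sb = np.cos(a), np.sin(a), np.cos(b), np.sin(b)
    Rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    Rx = np.array([[1, 0, 0], [0, cb, -sb], [0, sb, cb]])
    return Rx @ Rz, np.array([0.5, -0.3, 0.2]) * k


def build_geometry_fixture(methylated: bool,
                           n_models: int = 10) -> StructureEnsemble:
    """Idealized C-G base pair plus a tyrosine side-chain fragment.

    The cytosine (chain B, DC 4) pairs a guanine (chain C, DG 104); the
    tyrosine ring (chain A, TYR 154) is placed with its nearest ring
    carbon at the C...C van der Waals sum plus 0.2 A from the cytosine
    C5, along the direction a 5-methyl substituent would occupy.  With
    ``methylated`` the C5M carbon is added first, so the same placement
    is evaluated with the methyl group present.  Models differ only by a
    deterministic rigid transform, which preserves all distances.
    """
    atoms: list[Atom] = []
    serial = 1
    for name, (x, y) in _CYTOSINE_XY.items():
        atoms.append(Atom(serial, name, "DC", "B", 4, x, y, 0.0))
        serial += 1
    for name, (x, y) in _GUANINE_XY.items():
        atoms.append(Atom(serial, name, "DG", "C", 104, x, -y, 0.0))
        serial += 1
    cy = {a.name: a.coords for a in atoms if a.chain == "B"}
    for name, xyz in _tyrosine_fragment(cy["C4"], cy["C5"], cy["C6"]).items():
        atoms.append(Atom(serial, name, "TYR", "A", 154,
                          xyz[0], xyz[1], xyz[2]))
        serial += 1

    if methylated:
        atoms = methylate_cytosine(atoms, "B", 4)

    models = []
    for k in range(n_models):
        R, t = _rigid_transform(k)
        moved = []
        for a in atoms:
            xyz = R @ a.coords + t
            moved.append(Atom(a.serial, a.name, a.resname, a.chain, a.resnum,
                              float(xyz[0]), float(xyz[1]), float(xyz[2]),
                              element=a.element))
        models.append(moved)
    return StructureEnsemble(models)
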