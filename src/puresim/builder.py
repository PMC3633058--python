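"""Programmatic construction of the coupled transcription/translation
(PURE-system) reaction network.

The GFP gene is discretized into elongation *sites* of 80 bp (~27 codons).
Polymerase and ribosome progress is modeled as transitions between per-site
molecular states; free DNA/RNA site tokens (DNA1..DNAn, RNA1..RNAn) encode
site occupancy.  Within a site, nucleotide (transcription) and amino-acid
(translation) incorporation are explicit mass-action reactions whose
"dummy" tracker products (gtrN/atrN, TRANSLN) count progress; an immediate
reaction gates the transition to the next site once the site's stoichiometry
is complete and the next site token is free.  Because a moving polymerase
holds the tokens of its current and previous site (releasing site i-1 only
on entering i+1), elongating polymerases are spaced by at least one site
(>= 80 bp), and likewise ribosomes (>= 27 codons).

Only GTP and ATP are modeled (the two energy currencies: transcription uses
both; translation-factor hydrolysis uses GTP; tRNA charging uses ATP);
adding CTP/UTP roughly doubles the species count without changing the
outputs.  Amino acids, tRNAs, aminoacyl-tRNA synthetases and release
factors are each lumped into a single species.  NDK regenerates GTP from
the ATP pool.

Printed-magnitude rate constants for the per-site boxes are hard defaults;
constants the elongation boxes do not pin down (initiation, termination,
charging, factor recycling, NDK) and the standard species concentrations
are editable config defaults (see DEFAULT_RATE_CONSTANTS and
STANDARD_CONCENTRATIONS) chosen from typical cell-free/PURE literature
magnitudes, not fitted quantities.

Bimolecular constants are specified in deterministic units (M^-1 s^-1) and
converted to stochastic per-event constants by c = k / (N_A * V) at build
time; first-order constants are volume-independent; zero-order would scale
as k * N_A * V (none occur in the default network).
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field, replace

import yaml

from .model import ModelDocument
from .ssa import ImmediateReaction, KineticReaction, TimedEvent

__all__ = [
    "AVOGADRO",
    "GeneSpec",
    "PSComposition",
    "VesicleGeometry",
    "BuilderOptions",
    "ModelMetadata",
    "STANDARD_CONCENTRATIONS",
    "DEFAULT_RATE_CONSTANTS",
    "peptide_length_range",
    "combination_to_scalings",
    "concentration_to_count",
    "count_to_concentration",
    "volume_to_diameter",
    "diameter_to_volume",
    "build_transcription_box",
    "build_translation_box",
    "build_ps_model",
    "build_grid",
    "load_composition",
]

AVOGADRO = 6.02214076e23  # mol^-1

# Standard species concentrations (molar) by class.  These are config
# defaults in the spirit of a reconstituted transcription/translation mix:
# NTPs in the low-mM range, ribosomes ~1 uM, T7 RNA polymerase sub-uM,
# translation factors uM-range, NDK deliberately very low.  Every value is
# overridable via PSComposition / load_composition.
STANDARD_CONCENTRATIONS: dict[str, dict[str, float]] = {
    "dna": {
        "DNA": 100e-9,  # GFP template; DNA-titration studies override to <= 15 nM
    },
    "enzymes": {
        "T7": 1.5e-6,       # T7 RNA polymerase (added in excess over templates)
        "Rib": 1.2e-6,      # 70S ribosomes
        "EFtuGTP": 10e-6,   # EF-Tu, initialized GTP-charged
        "EFgGTP": 0.5e-6,   # EF-G, initialized GTP-charged
        "ARS": 0.3e-6,      # lumped aminoacyl-tRNA synthetase
        "RF": 0.5e-6,       # lumped release factor
        "NDK": 0.05e-6,     # nucleotide diphosphate kinase (very low)
    },
    "consumables": {
        "GTP": 2e-3,
        "ATP": 2e-3,
        "AA": 6e-3,         # lumped amino-acid pool (20 x 0.3 mM)
        "tRNA": 100e-6,     # lumped tRNA pool
    },
}

# Rate constants.  Per-site elongation constants are the printed box values;
# bimolecular entries are deterministic M^-1 s^-1 (converted per volume).
DEFAULT_RATE_CONSTANTS: dict[str, float] = {
    # transcription elongation box (per 80-bp site)
    "tx_ntp_bind": 1e6,        # T7ELGT_i + GTP / T7ELAT_i + ATP association
    "tx_ntp_incorp": 28.0,     # nucleotide incorporation, s^-1
    # translation elongation box (per 27-codon site)
    "tl_tern_bind": 1e8,       # eR_i + EFaRGTP (ternary complex delivery)
    "tl_tern_unbind": 79.0,
    "tl_accept": 207.0,
    "tl_reject": 3.45,
    "tl_hydrolysis": 100.0,    # EF-Tu GTP hydrolysis, releases Pi
    "tl_conform": 638.0,
    "tl_tu_release": 15.0,     # EF-Tu(GDP) leaves the ribosome
    "tl_peptidyl": 20.0,       # peptidyl transfer / tRNA accommodation
    "tl_efg_bind": 1.5e8,      # eRa_i-tRNA + EF-G(GTP)
    "tl_efg_unbind": 140.0,
    "tl_efg_hydrolysis": 250.0,
    "tl_translocate": 20.0,    # yields the TRANSL_i tracker
    # machinery not pinned down by the elongation boxes (config defaults)
    "tx_initiation": 1e7,      # T7 + promoter-bearing site, M^-1 s^-1
    "tl_initiation": 1e5,      # ribosome + RBS-bearing RNA site, M^-1 s^-1
    # effective maturation of the bound initiation complex into an
    # elongating ribosome; lumps 30S positioning, mRNA unfolding and 50S
    # joining, and makes initiation the rate-limiting step of protein
    # production (ribosome utilization in reconstituted systems is low)
    "tl_start": 1e-3,          # s^-1
    "tl_termination": 1e7,     # release-factor-assisted release, M^-1 s^-1
    "charge_atp": 1e6,         # ARS + ATP
    "charge_aa": 1e6,          # ARS(ATP) + AA
    "charge_trna": 1e6,        # ARS(aa) + tRNA
    "ternary_form": 1e6,       # EFtuGTP + aatRNA
    "tu_exchange": 1e6,        # EFtuGDP + GTP
    "efg_exchange": 1e6,       # EFg + GTP
    "ndk_atp": 1e6,            # NDK + ATP -> NDK~P + ADP
    "ndk_gdp": 1e6,            # NDK~P + GDP -> NDK + GTP
    "rib_inactivation": 5e-4,  # first-order Rib decay, switched on by a timed event
}


@dataclass
class GeneSpec:
    """Discretization of the coding sequence into elongation sites.

    Defaults describe a 720-bp GFP template: 9 sites of 80 bp, ~27 codons
    per site, and 20 G + 20 A incorporations per site (only the two modeled
    nucleotide classes).  A length that is not a multiple of site_bp keeps
    ``length_bp // site_bp`` sites and absorbs the remainder into the last
    site's incorporation counts.
    """

    length_bp: int = 720
    site_bp: int = 80
    codons_per_step: int = 27
    incorporations_per_site: int = 20

    def __post_init__(self):
        if self.length_bp <= 0 or self.site_bp <= 0:
            raise ValueError("gene length and site size must be positive")
        if self.n_sites < 2:
            raise ValueError(
                f"gene of {self.length_bp} bp gives fewer than 2 sites of {self.site_bp} bp"
            )

    @property
    def n_sites(self) -> int:
        return self.length_bp // self.site_bp

    def incorporations_at(self, site_index: int) -> int:
        """G (equally A) incorporations gating site ``site_index``."""
        if site_index != self.n_sites:
            return self.incorporations_per_site
        remainder = self.length_bp - self.n_sites * self.site_bp
        extra = round(remainder * self.incorporations_per_site / self.site_bp)
        return self.incorporations_per_site + extra


@dataclass
class PSComposition:
    """Standard concentrations by class plus the 3-digit combination code.

    Each digit of the code scales one class (DNA, enzymes, consumables in
    that order): digit d means a fraction (d+1)/3 of the standard
    concentration.
    """

    standard_concentrations: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in STANDARD_CONCENTRATIONS.items()}
    )
    combination_code: str = "222"

    def __post_init__(self):
        expected = {"dna", "enzymes", "consumables"}
        if set(self.standard_concentrations) != expected:
            raise ValueError(f"concentration classes must be exactly {sorted(expected)}")
        seen: set[str] = set()
        for cls, table in self.standard_concentrations.items():
            for name, conc in table.items():
                if name in seen:
                    raise ValueError(f"species {name!r} assigned to more than one class")
                if conc < 0:
                    raise ValueError(f"negative concentration for {name!r}")
                seen.add(name)
        combination_to_scalings(self.combination_code)  # validates the code

    def scaled(self, volume: float) -> dict[str, dict[str, int]]:
        """Scaled initial copy numbers per class at the given volume."""
        dna_s, enz_s, con_s = combination_to_scalings(self.combination_code)
        scale = {"dna": dna_s, "enzymes": enz_s, "consumables": con_s}
        return {
            cls: {
                name: concentration_to_count(scale[cls] * conc, volume)
                for name, conc in table.items()
            }
            for cls, table in self.standard_concentrations.items()
        }


@dataclass
class VesicleGeometry:
    """Spherical reactor volume in liters; diameter derived."""

    volume: float  # liters

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError("volume must be positive")

    @property
    def diameter(self) -> float:
        """Sphere diameter in meters."""
        return volume_to_diameter(self.volume)

    @classmethod
    def from_diameter(cls, diameter_m: float) -> "VesicleGeometry":
        return cls(volume=diameter_to_volume(diameter_m))


@dataclass
class BuilderOptions:
    ribosome_inactivation: bool = True
    inactivation_onset: float = 10800.0  # s ("circa 3 hours")
    inactivation_rate: float = DEFAULT_RATE_CONSTANTS["rib_inactivation"]  # s^-1
    include_ndk: bool = True
    min_one_dna: bool = False  # force >= 1 template copy after discretization
    rate_constants: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RATE_CONSTANTS)
    )

    def __post_init__(self):
        if self.ribosome_inactivation and self.inactivation_onset <= 0:
            raise ValueError("inactivation onset must be positive when enabled")


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------


def peptide_length_range(pept_index: int, gene: GeneSpec | None = None) -> tuple[int, int]:
    """Length bounds (aa) of a nascent peptide whose ribosome carries the
    PEPT_i marker: it has passed gate i but not gate i+1, so its length is
    between 27*i and 27*(i+1) - 1 amino acids (for the default 27-codon
    step)."""
    gene = gene or GeneSpec()
    if pept_index < 1:
        raise ValueError("peptide marker index must be >= 1")
    c = gene.codons_per_step
    return c * pept_index, c * (pept_index + 1) - 1


def combination_to_scalings(code: str) -> tuple[float, float, float]:
    """3-digit code over {0,1,2} -> (dna, enzymes, consumables) fractions.

    Digit d scales its class to (d+1)/3 of standard: 0 -> 1/3, 1 -> 2/3,
    2 -> 3/3.
    """
    if not re.fullmatch(r"[012]{3}", code or ""):
        raise ValueError(f"combination code must match [012]{{3}}, got {code!r}")
    return tuple((int(d) + 1) / 3 for d in code)  # type: ignore[return-value]


def concentration_to_count(conc: float, volume: float) -> int:
    """Molar concentration -> integer molecule count at the given volume."""
    if conc < 0:
        raise ValueError("negative concentration")
    if volume <= 0:
        raise ValueError("volume must be positive")
    return round(conc * AVOGADRO * volume)


def count_to_concentration(count: float, volume: float) -> float:
    """Molecule count -> molar concentration at the given volume."""
    if count < 0:
        raise ValueError("negative count")
    if volume <= 0:
        raise ValueError("volume must be positive")
    return count / (AVOGADRO * volume)


def volume_to_diameter(volume_l: float) -> float:
    """Sphere diameter (m) of a reactor of ``volume_l`` liters."""
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    return (6.0 * volume_l * 1e-3 / math.pi) ** (1.0 / 3.0)


def diameter_to_volume(diameter_m: float) -> float:
    """Inverse of volume_to_diameter: sphere volume in liters."""
    if diameter_m <= 0:
        raise ValueError("diameter must be positive")
    return math.pi * diameter_m**3 / 6.0 * 1e3


# ---------------------------------------------------------------------------
# per-site reaction boxes (rate constants in deterministic units; conversion
# to stochastic constants happens in build_ps_model)
# ---------------------------------------------------------------------------


def build_transcription_box(
    site_index: int, gene: GeneSpec, rates: dict[str, float] | None = None
) -> tuple[list[KineticReaction], list[ImmediateReaction]]:
    """Reactions for polymerase elongation through one 80-bp site.

    Per site i: GTP binding (2nd order), GTP incorporation (1st order,
    releasing Pi and the tracker gtr_i), the ATP pair likewise, and the
    immediate gate consuming 20 gtr_i + 20 atr_i that advances the
    polymerase state to site i+1, emits the RNA_i site token and releases
    the DNA site two behind the newly occupied one.  The first site's gate
    has no site to release; the last site's gate terminates: it frees the
    polymerase and both held DNA sites.
    """
    k = rates or DEFAULT_RATE_CONSTANTS
    n = gene.n_sites
    i = site_index
    if not 1 <= i <= n:
        raise ValueError(f"site index {i} out of range 1..{n}")
    kin = [
        KineticReaction(f"tx_gbind_{i}", k["tx_ntp_bind"],
                        [(f"T7ELGT{i}", 1), ("GTP", 1)], [(f"T7pregEL{i}", 1)]),
        KineticReaction(f"tx_gincorp_{i}", k["tx_ntp_incorp"],
                        [(f"T7pregEL{i}", 1)],
                        [(f"T7ELAT{i}", 1), ("Pi", 1), (f"gtr{i}", 1)]),
        KineticReaction(f"tx_abind_{i}", k["tx_ntp_bind"],
                        [(f"T7ELAT{i}", 1), ("ATP", 1)], [(f"T7preaEL{i}", 1)]),
        KineticReaction(f"tx_aincorp_{i}", k["tx_ntp_incorp"],
                        [(f"T7preaEL{i}", 1)],
                        [(f"T7ELGT{i}", 1), ("Pi", 1), (f"atr{i}", 1)]),
    ]
    m = gene.incorporations_at(i)
    trigger = [(f"gtr{i}", m), (f"atr{i}", m), (f"T7ELGT{i}", 1)]
    if i < n:
        trigger.append((f"DNA{i + 1}", 1))
        products = [(f"T7ELGT{i + 1}", 1), (f"RNA{i}", 1)]
        if i > 1:
            products.append((f"DNA{i - 1}", 1))
    else:
        products = [("T7", 1), (f"RNA{n}", 1), (f"DNA{n - 1}", 1), (f"DNA{n}", 1)]
    imm = [ImmediateReaction(f"tx_gate_{i}", trigger, products)]
    return kin, imm


def build_translation_box(
    site_index: int, gene: GeneSpec, rates: dict[str, float] | None = None
) -> tuple[list[KineticReaction], list[ImmediateReaction]]:
    """Reactions for ribosome elongation through one ~27-codon site.

    The kinetic cycle delivers an aminoacyl-tRNA ternary complex (EFaRGTP),
    hydrolyzes EF-Tu's GTP, forms the peptide bond and translocates with
    EF-G, producing one TRANSL_i tracker per amino acid.  After 27
    trackers the immediate gate advances the ribosome to site i+1,
    consuming the RNA site ahead, converting the PEPT length marker and
    releasing the RNA site behind.  The final site's gate yields a
    pre-termination ribosome (eRterm) whose release-factor-assisted
    termination reaction (added by build_ps_model) emits the finished GFP.
    """
    k = rates or DEFAULT_RATE_CONSTANTS
    n = gene.n_sites
    i = site_index
    if not 1 <= i <= n:
        raise ValueError(f"site index {i} out of range 1..{n}")
    kin = [
        KineticReaction(f"tl_tern_bind_{i}", k["tl_tern_bind"],
                        [(f"eR{i}", 1), ("EFaRGTP", 1)], [(f"EXpre{i}", 1)]),
        KineticReaction(f"tl_tern_unbind_{i}", k["tl_tern_unbind"],
                        [(f"EXpre{i}", 1)], [(f"eR{i}", 1), ("EFaRGTP", 1)]),
        KineticReaction(f"tl_accept_{i}", k["tl_accept"],
                        [(f"EXpre{i}", 1)], [(f"EX{i}", 1)]),
        KineticReaction(f"tl_reject_{i}", k["tl_reject"],
                        [(f"EX{i}", 1)], [(f"EXpre{i}", 1)]),
        KineticReaction(f"tl_hyd_{i}", k["tl_hydrolysis"],
                        [(f"EX{i}", 1)], [(f"EX{i}GDP", 1), ("Pi", 1)]),
        KineticReaction(f"tl_conf_{i}", k["tl_conform"],
                        [(f"EX{i}GDP", 1)], [(f"eRa{i}GDP", 1)]),
        KineticReaction(f"tl_turel_{i}", k["tl_tu_release"],
                        [(f"eRa{i}GDP", 1)], [(f"eRa{i}", 1), ("EFtuGDP", 1)]),
        KineticReaction(f"tl_pep_{i}", k["tl_peptidyl"],
                        [(f"eRa{i}", 1)], [(f"eRa{i}tRNA", 1)]),
        KineticReaction(f"tl_efg_bind_{i}", k["tl_efg_bind"],
                        [(f"eRa{i}tRNA", 1), ("EFgGTP", 1)], [(f"EXbpre{i}", 1)]),
        KineticReaction(f"tl_efg_unbind_{i}", k["tl_efg_unbind"],
                        [(f"EXbpre{i}", 1)], [(f"eRa{i}tRNA", 1), ("EFgGTP", 1)]),
        KineticReaction(f"tl_efg_hyd_{i}", k["tl_efg_hydrolysis"],
                        [(f"EXbpre{i}", 1)],
                        [(f"EXb{i}", 1), ("EFg", 1), ("GDP", 1), ("Pi", 1)]),
        KineticReaction(f"tl_transloc_{i}", k["tl_translocate"],
                        [(f"EXb{i}", 1)],
                        [(f"eR{i}", 1), ("tRNA", 1), (f"TRANSL{i}", 1)]),
    ]
    cg = gene.codons_per_step
    trigger = [(f"TRANSL{i}", cg)]
    if i < n:
        trigger.append((f"RNA{i + 1}", 1))
        if i > 1:
            trigger.append((f"PEPT{i - 1}", 1))
        trigger.append((f"eR{i}", 1))
        products = [(f"eR{i + 1}", 1), (f"PEPT{i}", 1)]
        if i > 1:
            products.append((f"RNA{i - 1}", 1))
    else:
        trigger += [(f"PEPT{n - 1}", 1), (f"eR{n}", 1)]
        products = [("eRterm", 1)]
    imm = [ImmediateReaction(f"tl_gate_{i}", trigger, products)]
    return kin, imm


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------


def _global_reactions(n: int, k: dict[str, float], include_ndk: bool,
                      rib_inact: bool) -> list[KineticReaction]:
    kin = [
        # initiation / termination
        KineticReaction("tx_init", k["tx_initiation"],
                        [("T7", 1), ("DNA1", 1)], [("T7ELGT1", 1)]),
        # two-step initiation: the ribosome parks on the RBS site (blocking
        # it) and matures slowly into an elongating ribosome
        KineticReaction("tl_init", k["tl_initiation"],
                        [("Rib", 1), ("RNA1", 1)], [("IC1", 1)]),
        KineticReaction("tl_start", k["tl_start"], [("IC1", 1)], [("eR1", 1)]),
        KineticReaction("tl_term", k["tl_termination"],
                        [("eRterm", 1), ("RF", 1)],
                        [("Rib", 1), ("RF", 1), ("GFP", 1),
                         (f"RNA{n - 1}", 1), (f"RNA{n}", 1)]),
        # lumped ATP-consuming aminoacyl-tRNA charging and ternary-complex cycle
        KineticReaction("chg_atp", k["charge_atp"],
                        [("ARS", 1), ("ATP", 1)], [("ARSATP", 1)]),
        KineticReaction("chg_aa", k["charge_aa"],
                        [("ARSATP", 1), ("AA", 1)],
                        [("ARSaa", 1), ("AMP", 1), ("PPi", 1)]),
        KineticReaction("chg_trna", k["charge_trna"],
                        [("ARSaa", 1), ("tRNA", 1)], [("ARS", 1), ("aatRNA", 1)]),
        KineticReaction("tern_form", k["ternary_form"],
                        [("EFtuGTP", 1), ("aatRNA", 1)], [("EFaRGTP", 1)]),
        # factor recycling (GTP-consuming nucleotide exchange)
        KineticReaction("tu_exchange", k["tu_exchange"],
                        [("EFtuGDP", 1), ("GTP", 1)], [("EFtuGTP", 1), ("GDP", 1)]),
        KineticReaction("efg_exchange", k["efg_exchange"],
                        [("EFg", 1), ("GTP", 1)], [("EFgGTP", 1)]),
    ]
    if include_ndk:
        # ping-pong phosphotransfer ATP + GDP <=> ADP + GTP (Keq ~ 1): both
        # half-reactions reversible so net regeneration follows the
        # nucleotide free-energy gradient instead of draining the ATP pool
        kin += [
            KineticReaction("ndk_atp", k["ndk_atp"],
                            [("NDK", 1), ("ATP", 1)], [("NDKP", 1), ("ADP", 1)]),
            KineticReaction("ndk_atp_rev", k["ndk_atp"],
                            [("NDKP", 1), ("ADP", 1)], [("NDK", 1), ("ATP", 1)]),
            KineticReaction("ndk_gdp", k["ndk_gdp"],
                            [("NDKP", 1), ("GDP", 1)], [("NDK", 1), ("GTP", 1)]),
            KineticReaction("ndk_gdp_rev", k["ndk_gdp"],
                            [("NDK", 1), ("GTP", 1)], [("NDKP", 1), ("GDP", 1)]),
        ]
    if rib_inact:
        # rate starts at 0; a timed event switches it on at the onset time
        kin.append(KineticReaction("rib_inact", 0.0, [("Rib", 1)], [("RibX", 1)]))
    return kin


def _to_stochastic(c_deterministic: float, molecularity: int, volume: float) -> float:
    """Deterministic -> stochastic rate constant at volume V (liters)."""
    nav = AVOGADRO * volume
    if molecularity == 0:
        return c_deterministic * nav
    return c_deterministic / nav ** (molecularity - 1)


def build_ps_model(
    gene: GeneSpec | None = None,
    comp: PSComposition | None = None,
    geom: VesicleGeometry | None = None,
    opts: BuilderOptions | None = None,
) -> ModelDocument:
    """Assemble the full transcription/translation network as a ModelDocument.

    Initial copy numbers are the class-scaled standard concentrations
    discretized at the vesicle volume; every intermediate species is
    declared with count 0.  Bimolecular rate constants are converted to
    stochastic per-event constants for the chosen volume.
    """
    gene = gene or GeneSpec()
    comp = comp or PSComposition()
    geom = geom or VesicleGeometry(volume=1e-16)
    opts = opts or BuilderOptions()
    k = opts.rate_constants
    n = gene.n_sites
    V = geom.volume

    kin: list[KineticReaction] = []
    imm: list[ImmediateReaction] = []
    for i in range(1, n + 1):
        bk, bi = build_transcription_box(i, gene, k)
        kin += bk
        imm += bi
    for i in range(1, n + 1):
        bk, bi = build_translation_box(i, gene, k)
        kin += bk
        imm += bi
    kin += _global_reactions(n, k, opts.include_ndk, opts.ribosome_inactivation)

    # convert deterministic constants to stochastic per-event constants
    for r in kin:
        molecularity = sum(nu for _, nu in r.reactants)
        r.c = _to_stochastic(r.c, molecularity, V)

    counts = comp.scaled(V)
    n_dna = counts["dna"]["DNA"]
    if opts.min_one_dna and comp.standard_concentrations["dna"]["DNA"] > 0:
        n_dna = max(1, n_dna)

    init: dict[str, int] = {}
    for i in range(1, n + 1):
        init[f"DNA{i}"] = n_dna
    for cls in ("enzymes", "consumables"):
        for name, cnt in counts[cls].items():
            if name == "NDK" and not opts.include_ndk:
                continue
            init[name] = cnt
    # declare every intermediate species explicitly at 0
    for r in kin:
        for name, _nu in r.reactants + r.products:
            init.setdefault(name, 0)
    for im in imm:
        for name, _nu in im.trigger + im.products:
            init.setdefault(name, 0)

    events: list[TimedEvent] = []
    if opts.ribosome_inactivation:
        events.append(TimedEvent(time=opts.inactivation_onset, kind="rate",
                                 reaction_id="rib_inact",
                                 value=opts.inactivation_rate))

    doc = ModelDocument(
        initial_counts=init,
        kinetic_reactions=kin,
        immediate_reactions=imm,
        timed_events=events,
        comments=[
            f"PS transcription/translation model: {gene.length_bp} bp gene, "
            f"{n} sites of {gene.site_bp} bp",
            f"combination {comp.combination_code}, volume {V:g} L "
            f"(diameter {geom.diameter * 1e9:.0f} nm)",
            f"DNA template copies: {n_dna}",
        ],
    )
    return doc


def build_grid(
    gene: GeneSpec | None = None,
    comp_template: PSComposition | None = None,
    geom: VesicleGeometry | None = None,
    opts: BuilderOptions | None = None,
) -> dict[str, ModelDocument]:
    """One model per combination code, "000".."222" in lexicographic order."""
    comp_template = comp_template or PSComposition()
    out: dict[str, ModelDocument] = {}
    for digits in itertools.product("012", repeat=3):
        code = "".join(digits)
        comp = replace(comp_template, combination_code=code)
        out[code] = build_ps_model(gene, comp, geom, opts)
    return out


def load_composition(path) -> PSComposition:
    """Read standard concentrations (and optionally a combination code) from
    a YAML config with sections dna/enzymes/consumables."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    code = data.pop("combination_code", "222")
    conc = {cls: {str(kk): float(vv) for kk, vv in (data.get(cls) or {}).items()}
            for cls in ("dna", "enzymes", "consumables")}
    return PSComposition(standard_concentrations=conc, combination_code=code)


# ---------------------------------------------------------------------------
# metadata: classify species/reactions of a built (or round-tripped) model
# ---------------------------------------------------------------------------

_POLYMERASE_STATE = re.compile(r"^T7(ELGT|pregEL|ELAT|preaEL)\d+$")
_RIBOSOME_STATE = re.compile(
    r"^(eR\d+|EXpre\d+|EX\d+|EX\d+GDP|eRa\d+GDP|eRa\d+|eRa\d+tRNA|EXbpre\d+|EXb\d+|eRterm)$"
)
_TRACKER = re.compile(r"^(gtr|atr)\d+$")


@dataclass
class ModelMetadata:
    """Derived classification of a PS model's species and reactions, used by
    the kinetics/energy analysis.  Works on builder output and on models
    round-tripped through the text dialect (classification keys off the
    builder's systematic naming)."""

    active_polymerase_species: list[str]
    active_ribosome_species: list[str]
    tracker_species: list[str]
    incorporation_reactions: list[str]
    translocation_gates: list[str]
    transcription_gates: list[str]
    codons_per_gate: int
    protein_species: str
    # reaction id -> (nucleotide, process); process in
    # {"transcription", "translation", "charging", "ndk"}
    ntp_consumption_tags: dict[str, tuple[str, str]]
    # reaction id -> nucleotide it regenerates (NDK phosphotransfer)
    ntp_regeneration_tags: dict[str, str]
    untagged_ntp_reactions: list[str]

    @classmethod
    def from_document(cls, doc: ModelDocument) -> "ModelMetadata":
        poly = [s for s in doc.species if _POLYMERASE_STATE.match(s)]
        rib = [s for s in doc.species if _RIBOSOME_STATE.match(s)]
        trackers = [s for s in doc.species if _TRACKER.match(s)]

        incorporation = [r.id for r in doc.kinetic_reactions
                         if any(_TRACKER.match(name) for name, _ in r.products)]
        tl_gates, tx_gates = [], []
        codons = 0
        for im in doc.immediate_reactions:
            trig = dict(im.trigger)
            if any(name.startswith("TRANSL") for name in trig):
                tl_gates.append(im.id)
                codons = max(codons, max(nu for name, nu in im.trigger
                                         if name.startswith("TRANSL")))
            elif any(_TRACKER.match(name) for name in trig):
                tx_gates.append(im.id)

        tags: dict[str, tuple[str, str]] = {}
        regen: dict[str, str] = {}
        untagged: list[str] = []
        for r in doc.kinetic_reactions:
            consumed = {name: nu for name, nu in r.reactants}
            produced = {name: nu for name, nu in r.products}
            partners = set(consumed)
            for ntp in ("GTP", "ATP"):
                net = consumed.get(ntp, 0) - produced.get(ntp, 0)
                if net <= 0:
                    if net < 0 and any(p.startswith("NDK") for p in partners):
                        regen[r.id] = ntp
                    continue
                if any(p.startswith("T7") for p in partners):
                    tags[r.id] = (ntp, "transcription")
                elif any(p.startswith(("EFtu", "EFg", "eR")) for p in partners):
                    tags[r.id] = (ntp, "translation")
                elif any(p.startswith("ARS") for p in partners):
                    tags[r.id] = (ntp, "charging")
                elif any(p.startswith("NDK") for p in partners):
                    tags[r.id] = (ntp, "ndk")
                else:
                    untagged.append(r.id)

        return cls(
            active_polymerase_species=poly,
            active_ribosome_species=rib,
            tracker_species=trackers,
            incorporation_reactions=incorporation,
            translocation_gates=tl_gates,
            transcription_gates=tx_gates,
            codons_per_gate=codons or 27,
            protein_species="GFP",
            ntp_consumption_tags=tags,
            ntp_regeneration_tags=regen,
            untagged_ntp_reactions=untagged,
        )
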