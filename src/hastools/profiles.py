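"""Default heme *a* synthase (HAS) type profiles and published census constants.

The HAS family splits into seven types distinguished by transmembrane-helix
count (4 for the short archaeal type 1A, 8 for everything else), by which
periplasmic loops carry a conserved cysteine pair (ECL1 and/or ECL3), and by
the residues observed at the two catalytic motifs:

* the helix-II motif ``E57–X1–X2–H1–R`` (B. subtilis numbering), whose
  glutamate is strictly conserved and whose X positions are type-diagnostic;
* the "mirror" motif ``X1–X2–X3–H3–X4`` on helix VI, generally less conserved
  and absent from the C-terminally truncated type 1A.

The per-type residue frequencies encoded here are the published conservation
percentages for this family; positions without a reported consensus get a
uniform background over the twenty amino acids, and any residual probability
mass is spread uniformly over the unlisted residues. These profiles drive the
synthetic-sequence generator and also provide the shipped reference panels for
the classifier.

The module also records the published family census (per-type sequence counts,
fusion and synteny count pairs), from which the default neighborhood
co-occurrence model is derived.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import AMINO_ACIDS

HAS_TYPES = ("0", "1A", "1A*", "1B", "1C", "1D", "2")

#: which extracellular (periplasmic) loops carry a conserved Cys pair, per type
CYS_PAIR_TABLE: dict[str, frozenset[str]] = {
    "0": frozenset(),
    "1A": frozenset({"ECL1"}),
    "1A*": frozenset({"ECL1"}),
    "1B": frozenset({"ECL1", "ECL3"}),
    "1C": frozenset({"ECL1"}),
    "1D": frozenset(),
    "2": frozenset(),
}

PRIMARY_SLOTS = ("E57", "X1", "X2", "H1", "R")
MIRROR_SLOTS = ("mX1", "mX2", "mX3", "H3", "mX4")

#: reference histidine anchors outside the two motifs: H2 on helix IV, H4 on
#: helix VIII (His123 / His278 in B. subtilis numbering); fixed constants.
H2_RESIDUE = "H"
H4_RESIDUE = "H"


def _freq(main: dict[str, float] | None = None) -> dict[str, float]:
    """Frequency table: listed residues keep their mass, the residual is spread
    uniformly over the remaining amino acids. ``None`` -> uniform over 20."""
    main = dict(main or {})
    for r in main:
        if r not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {r!r}")
    residual = 1.0 - sum(main.values())
    if residual < -1e-9:
        raise ValueError("frequencies exceed 1")
    others = [a for a in AMINO_ACIDS if a not in main]
    out = dict(main)
    for a in others:
        out[a] = residual / len(others)
    return out


@dataclass(frozen=True)
class TypeProfile:
    """Generative description of one HAS type."""

    type_label: str
    n_tm: int
    cys_pairs: frozenset[str]
    motif_freqs: dict[str, dict[str, float]]
    #: loop-length distributions, key "default" plus per-loop overrides
    #: ("ECL1", "ECL3", ...); value = (mean, sd, min)
    loop_length_dist: dict[str, tuple[float, float, int]]
    length_range: tuple[int, int]
    cys_spacing: tuple[int, int] = (4, 8)

    def __post_init__(self) -> None:
        if self.type_label not in HAS_TYPES:
            raise ValueError(f"unknown HAS type {self.type_label!r}")
        if self.cys_pairs != CYS_PAIR_TABLE[self.type_label]:
            raise ValueError(
                f"cys_pairs for type {self.type_label} must be "
                f"{set(CYS_PAIR_TABLE[self.type_label])}"
            )
        if (self.n_tm == 4) != (self.type_label == "1A"):
            raise ValueError("n_tm must be 4 exactly for type 1A")
        if "default" not in self.loop_length_dist:
            raise ValueError("loop_length_dist needs a 'default' entry")
        for slot, freqs in self.motif_freqs.items():
            s = sum(freqs.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{self.type_label}/{slot}: frequencies sum to {s}")

    @property
    def has_mirror(self) -> bool:
        return self.n_tm >= 6

    def loop_dist(self, key: str) -> tuple[float, float, int]:
        return self.loop_length_dist.get(key, self.loop_length_dist["default"])


def _primary(x1=None, x2=None, h1=None) -> dict[str, dict[str, float]]:
    return {
        "E57": _freq({"E": 1.0}),
        "X1": _freq(x1),
        "X2": _freq(x2),
        "H1": _freq(h1 if h1 is not None else {"H": 1.0}),
        "R": _freq({"R": 1.0}),
    }


def _mirror(mx1=None, mx2=None, mx3=None, h3=None, mx4=None) -> dict[str, dict[str, float]]:
    return {
        "mX1": _freq(mx1),
        "mX2": _freq(mx2),
        "mX3": _freq(mx3),
        "H3": _freq(h3 if h3 is not None else {"H": 1.0}),
        "mX4": _freq(mx4),
    }


def _loops(default, **overrides) -> dict[str, tuple[float, float, int]]:
    d = {"default": default}
    d.update(overrides)
    return d


def default_profiles() -> dict[str, TypeProfile]:
    """The shipped per-type profiles.

    Helix-II motif conservation: X1 is a tryptophan in types 1A (85%),
    1A* (96%) and 2 (74%); a histidine in 1D (98%); phenylalanine/tyrosine in
    1C (60%/25%); alanine in type 0 (75%); unconserved in 1B. X2 is variable
    except in 1A* (Phe 87%). H1 is histidine throughout, asparagine in 34% of
    type 1C. Mirror motif: type 0 shows Trp 55% / Phe 15% at its X1; type 1A*
    has Gln 93% at X1, Ala 59% at X2, Tyr 78% at X4 and phenylalanine instead
    of H3 in 55% of sequences; types 1D and 2 conserve Phe at X2 (63%/91%);
    X1 shows partial Gln (1B, 2), Arg (1C) or His (1D) conservation and X4 a
    partial arginine except in 1C (those partial levels are not quantified in
    the literature and default to 60–70%).

    Loop lengths: only the ordering "type 2 longest, type 0 shortest" is
    established; per-type means here are package defaults, configurable.
    """
    p: dict[str, TypeProfile] = {}
    p["0"] = TypeProfile(
        "0", 8, CYS_PAIR_TABLE["0"],
        {**_primary(x1={"A": 0.75}), **_mirror(mx1={"W": 0.55, "F": 0.15})},
        _loops((11.0, 2.0, 10)), (150, 320),
    )
    p["1A"] = TypeProfile(
        "1A", 4, CYS_PAIR_TABLE["1A"],
        _primary(x1={"W": 0.85}),  # truncated at the C-terminus: no mirror motif
        _loops((12.0, 3.0, 10), ECL1=(16.0, 2.0, 14)), (100, 199),
    )
    p["1A*"] = TypeProfile(
        "1A*", 8, CYS_PAIR_TABLE["1A*"],
        {
            **_primary(x1={"W": 0.96}, x2={"F": 0.87}),
            **_mirror(mx1={"Q": 0.93}, mx2={"A": 0.59},
                      h3={"F": 0.55, "H": 0.45}, mx4={"Y": 0.78}),
        },
        _loops((14.0, 3.0, 10), ECL1=(16.0, 2.0, 14)), (220, 400),
    )
    p["1B"] = TypeProfile(
        "1B", 8, CYS_PAIR_TABLE["1B"],
        {**_primary(), **_mirror(mx1={"Q": 0.60}, mx4={"R": 0.70})},
        _loops((18.0, 3.0, 10), ECL1=(18.0, 2.0, 14), ECL3=(18.0, 2.0, 14)),
        (230, 420),
    )
    p["1C"] = TypeProfile(
        "1C", 8, CYS_PAIR_TABLE["1C"],
        {
            **_primary(x1={"F": 0.60, "Y": 0.25}, h1={"N": 0.34, "H": 0.66}),
            **_mirror(mx1={"R": 0.60}),
        },
        _loops((12.0, 3.0, 10), ECL1=(16.0, 2.0, 14)), (200, 380),
    )
    p["1D"] = TypeProfile(
        "1D", 8, CYS_PAIR_TABLE["1D"],
        {**_primary(x1={"H": 0.98}),
         **_mirror(mx1={"H": 0.60}, mx2={"F": 0.63}, mx4={"R": 0.70})},
        _loops((22.0, 3.0, 10)), (240, 440),
    )
    p["2"] = TypeProfile(
        "2", 8, CYS_PAIR_TABLE["2"],
        {**_primary(x1={"W": 0.74}),
         **_mirror(mx1={"Q": 0.60}, mx2={"F": 0.91}, mx4={"R": 0.70})},
        _loops((30.0, 3.0, 10)), (260, 500),
    )
    return p


# --------------------------------------------------------------------------
# Published family census (used as default study conditions)
# --------------------------------------------------------------------------

#: per-type sequence counts in the published 35,307-assembly census
CENSUS_TYPE_COUNTS: dict[str, int] = {
    "0": 73, "1A": 273, "1A*": 121, "1B": 2339, "1C": 924, "1D": 42, "2": 4321,
}
CENSUS_TOTAL = 8093

#: (n_with, n_total) count pairs for heme o synthase in the ±5-gene window
CENSUS_HOS_COOCCURRENCE: dict[str, tuple[int, int]] = {
    "1B": (2140, 2339), "1C": (695, 924), "1D": (37, 42), "0": (12, 73),
}
#: cytochrome c oxidase subunits in the window
CENSUS_COX_COOCCURRENCE: dict[str, tuple[int, int]] = {
    "1A": (96, 273), "1B": (1371, 2339), "1D": (33, 42), "0": (18, 73),
    "1C": (112, 924), "2": (31, 4321),
}
#: type 1A records fused to heme o synthase
CENSUS_FUSION_1A: tuple[int, int] = (154, 273)
#: type 1A* records that are the only HAS-family record in their assembly
CENSUS_SOLE_1A_STAR: tuple[int, int] = (111, 121)

# neighbor-family label vocabulary
HOS = "heme_o_synthase"
COX = "cox_subunit"
HAS_LABEL = "heme_a_synthase"
NEIGHBOR_FAMILIES = (
    HOS, COX, "SCO1", "DUF1507", "pyruvate_carboxylase", "FtsW",
    "ribosomal_S9", "ribosomal_L13",
)
DECOY_FAMILIES = (
    "hypothetical_protein", "ABC_transporter", "DNA_polymerase_III",
    "MazG_pyrophosphohydrolase", "GNAT_acetyltransferase",
    "gamma_glutamyltranspeptidase", "malate_dehydrogenase",
    "replication_factor_C", "FAD_synthetase", "agmatinase",
)


@dataclass(frozen=True)
class NeighborModel:
    """Per-type neighbor co-occurrence probabilities in the ±5-gene window,
    plus the probability that a type 1A record is an HAS–HOS fusion."""

    probs: dict[str, dict[str, float]]
    fusion_prob: float = CENSUS_FUSION_1A[0] / CENSUS_FUSION_1A[1]

    def __post_init__(self) -> None:
        for t, fam in self.probs.items():
            for label, pr in fam.items():
                if not (0.0 <= pr <= 1.0):
                    raise ValueError(f"probability out of range for {t}/{label}")
        if not (0.0 <= self.fusion_prob <= 1.0):
            raise ValueError("fusion_prob out of range")

    def prob(self, has_type: str, label: str) -> float:
        return self.probs.get(has_type, {}).get(label, 0.0)


def default_neighbor_model() -> NeighborModel:
    """Co-occurrence defaults mirroring the published census fractions.

    HOS is nearly absent from type 1A/1A* neighborhoods (type 1A carries HOS as
    a fusion partner instead) and rare around type 2; those unprinted
    probabilities default to small values.
    """
    probs: dict[str, dict[str, float]] = {t: {} for t in HAS_TYPES}
    for t, (n, d) in CENSUS_HOS_COOCCURRENCE.items():
        probs[t][HOS] = n / d
    probs["1A"][HOS] = 0.0
    probs["1A*"][HOS] = 0.02
    probs["2"][HOS] = 0.05
    for t, (n, d) in CENSUS_COX_COOCCURRENCE.items():
        probs[t][COX] = n / d
    probs["1A*"][COX] = 0.02
    # flavor neighbors (qualitative associations, no printed fractions)
    for t in ("1B", "1C"):
        probs[t].update({"DUF1507": 0.3, "pyruvate_carboxylase": 0.2, "FtsW": 0.2})
    for t in ("1B", "1D", "2"):
        probs[t]["SCO1"] = 0.25 if t != "2" else 0.1
    probs["2"].update({"ribosomal_S9": 0.4, "ribosomal_L13": 0.4})
    probs["1A"]["malate_dehydrogenase"] = 0.3
    probs["1A*"].update({"malate_dehydrogenase": 0.3, "replication_factor_C": 0.3})
    return NeighborModel(probs=probs)


#: taxonomy pools per type: (domain, phylum, class); archaeal types 1A/1A*/0
#: versus the bacterial types, mirroring the published distribution
TAXONOMY_POOLS: dict[str, tuple[tuple[str, str, str], ...]] = {
    "1A": (("Archaea", "Thermoproteota", "Thermoprotei"),
           ("Archaea", "Euryarchaeota", "Halobacteria"),
           ("Archaea", "Ca_Marsarchaeota", "unclassified")),
    "1A*": (("Archaea", "Euryarchaeota", "Halobacteria"),),
    "0": (("Archaea", "Thermoproteota", "Thermoprotei"),
          ("Archaea", "Ca_Marsarchaeota", "unclassified"),
          ("Bacteria", "Pseudomonadota", "Gammaproteobacteria"),
          ("Bacteria", "Actinomycetota", "Actinomycetes")),
    "1B": (("Bacteria", "Pseudomonadota", "Alphaproteobacteria"),
           ("Bacteria", "Bacillota", "Bacilli"),
           ("Bacteria", "Spirochaetota", "Spirochaetia")),
    "1C": (("Bacteria", "Bacillota", "Bacilli"),
           ("Bacteria", "Actinomycetota", "Actinomycetes"),
           ("Archaea", "Ca_Thermoplasmatota", "Thermoplasmata")),
    "1D": (("Bacteria", "Bdellovibrionota", "Bdellovibrionia"),
           ("Bacteria", "Pseudomonadota", "Betaproteobacteria")),
    "2": (("Bacteria", "Pseudomonadota", "Alphaproteobacteria"),
          ("Bacteria", "Bacillota", "Bacilli"),
          ("Bacteria", "Gemmatimonadota", "Gemmatimonadetes")),
}
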