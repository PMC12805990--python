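"""Reporter-library designs: variant spaces, barcodes and construct assembly.

The assay measures the activity of a 10-bp abscisic acid-responsive element
(ABRE) embedded in a fixed 50-bp promoter fragment from the Arabidopsis
*ABI1* gene.  Two degenerate libraries mutate the element:

* ``ACGT-core``  — the 4 central positions of the element (the conserved
  ACGT core bound by bZIP transcription factors) are randomized (4^4 = 256
  variants);
* ``ACGT-flank`` — the 3 positions on either side of the core are
  randomized (4^6 = 4096 variants).

A third, non-degenerate ``35S-control`` library carries a constitutive
enhancer fragment in place of the ABRE promoter fragment and serves as an
activity reference.

Each reporter construct couples a variant to a random 12-bp barcode with a
``VNNVNNVNNVNN`` pattern (V = A/C/G); the barcode sits in the transcribed
reporter so that RNA reads identify the variant that produced them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "ALPHABET",
    "ABI1_CONTEXT",
    "BARCODE_LENGTH",
    "BARCODE_V_POSITIONS",
    "BARCODE_SPACE_SIZE",
    "LibraryDesign",
    "VariantSequence",
    "ConstructTemplate",
    "DEFAULT_TEMPLATE",
    "acgt_core_design",
    "acgt_flank_design",
    "control_35s_design",
    "enumerate_variants",
    "variant_key",
    "window_from_key",
    "is_valid_barcode",
    "validate_barcode",
    "assemble_construct",
    "reverse_complement",
    "DesignError",
    "WindowMismatchError",
    "BarcodePatternError",
]

ALPHABET = "ACGT"

#: 50-bp promoter fragment of the Arabidopsis ABI1 gene carrying the ABRE.
ABI1_CONTEXT = "TCTCCTTCCCATTTTCTTCGTCTACGTGTCGACCATCCACCGGTTTTTGT"

#: Synthetic 5' UTR (synJ) placed between the minimal promoter and the ATG.
SYNJ = "ACACGCTGGAATTCTAGTATACTAAACC"

#: 35S minimal promoter segment (-46..+5). Synthetic stand-in sequence with a
#: TATA box; only its length and fixed identity matter to the pipeline, and it
#: is configurable through ConstructTemplate.
MIN35S_SYNTHETIC = "CCCACTATCCTTCGCAAGACCCTTCCTCTATATAAGGAAGTTCATTTCATT"

#: First codons of the reporter ORF downstream of the barcode. Synthetic
#: stand-in; serves as the 3' anchor for barcode extraction.
REPORTER_PREFIX_SYNTHETIC = "GAAGATGCCAAGAACATCAAGAAGGGC"

#: 35S enhancer fragment (-96..-47) used by the control library. The assay
#: treats it as an opaque 50-mer; synthetic stand-in with as-1-like TGACG
#: repeats, configurable.
ENHANCER_35S_SYNTHETIC = "CTGACGTAAGGGATGACGCACAATCCCACTATCCTTCGCAAGACCCTTCC"

BARCODE_LENGTH = 12
BARCODE_V_POSITIONS = (0, 3, 6, 9)
#: 3^4 * 4^8 strings satisfy VNNVNNVNNVNN.
BARCODE_SPACE_SIZE = 3 ** 4 * 4 ** 8

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_code(bases) -> str:
    """IUPAC ambiguity code for a non-empty set of A/C/G/T bases."""
    return _IUPAC[frozenset(bases)]


class DesignError(ValueError):
    """Invalid library design or sequence inconsistent with a design."""


class WindowMismatchError(DesignError):
    """A 10-bp window disagrees with the design at a fixed position."""


class BarcodePatternError(ValueError):
    """A barcode string violates the VNNVNNVNNVNN pattern."""


@dataclass(frozen=True)
class LibraryDesign:
    """A variant library: fixed context plus degenerate window positions.

    Parameters
    ----------
    name:
        Library label, e.g. ``"ACGT-core"``.
    context:
        The 50-bp promoter fragment the variant window is embedded in.
    window_start:
        0-based offset of the 10-bp element window within ``context``.
    degenerate_positions:
        0-based offsets *within the window* that the library randomizes.
    core_positions:
        Offsets of the conserved ACGT core within the window.
    """

    name: str
    context: str = ABI1_CONTEXT
    window_start: int = 20
    degenerate_positions: tuple[int, ...] = ()
    core_positions: tuple[int, ...] = (3, 4, 5, 6)

    def __post_init__(self):
        if len(self.context) != 50:
            raise DesignError(f"context must be 50 bp, got {len(self.context)}")
        if set(self.context) - set(ALPHABET):
            raise DesignError("context contains non-ACGT characters")
        if not 0 <= self.window_start <= 40:
            raise DesignError("window must lie within the 50-bp context")
        object.__setattr__(
            self, "degenerate_positions",
            tuple(sorted(set(self.degenerate_positions))))
        if any(not 0 <= p < 10 for p in self.degenerate_positions):
            raise DesignError("degenerate positions must be window offsets 0..9")

    @property
    def window_end(self) -> int:
        return self.window_start + 10

    @property
    def wild_window(self) -> str:
        """The un-mutated 10-bp window as read from the context."""
        return self.context[self.window_start:self.window_end]

    @property
    def fixed_positions(self) -> tuple[int, ...]:
        return tuple(p for p in range(10) if p not in self.degenerate_positions)

    @property
    def key_length(self) -> int:
        return len(self.degenerate_positions)

    @property
    def n_variants(self) -> int:
        return 4 ** self.key_length


@dataclass(frozen=True)
class VariantSequence:
    """One realized library member: its key and full 10-bp window."""

    library: str
    key: str
    window10: str

    def __post_init__(self):
        if len(self.window10) != 10 or set(self.window10) - set(ALPHABET):
            raise DesignError(f"invalid window {self.window10!r}")


def acgt_core_design() -> LibraryDesign:
    """The 256-variant library randomizing the ACGT core (window offsets 3-6)."""
    return LibraryDesign(name="ACGT-core", degenerate_positions=(3, 4, 5, 6))


def acgt_flank_design() -> LibraryDesign:
    """The 4096-variant library randomizing the six flank positions.

    The four physically synthesized flank pools are modeled as one 4^6
    space; keys concatenate the upstream and downstream flank triplets
    (window ``GGGACGTTAT`` has key ``GGGTAT``).
    """
    return LibraryDesign(name="ACGT-flank", degenerate_positions=(0, 1, 2, 7, 8, 9))


def control_35s_design(context: str = ENHANCER_35S_SYNTHETIC) -> LibraryDesign:
    """The single-member control library carrying a 35S enhancer fragment."""
    return LibraryDesign(name="35S-control", context=context,
                         window_start=20, degenerate_positions=())


def window_from_key(design: LibraryDesign, key: str) -> str:
    """Realize the 10-bp window for a degenerate-position key."""
    if len(key) != design.key_length:
        raise DesignError(
            f"key {key!r} has length {len(key)}, design needs {design.key_length}")
    window = list(design.wild_window)
    for base, pos in zip(key, design.degenerate_positions):
        if base not in ALPHABET:
            raise DesignError(f"non-ACGT base {base!r} in key")
        window[pos] = base
    return "".join(window)


def variant_key(window10: str, design: LibraryDesign) -> str:
    """Read the variant key off a 10-bp window, enforcing fixed positions.

    Raises
    ------
    WindowMismatchError
        If any fixed window position disagrees with the design context
        (the signature of a read that is not perfectly matched).
    DesignError
        If the window is not a 10-mer over A/C/G/T.
    """
    if len(window10) != 10:
        raise DesignError(f"window must be 10 bp, got {len(window10)}")
    if set(window10) - set(ALPHABET):
        raise DesignError(f"non-ACGT character in window {window10!r}")
    wild = design.wild_window
    for pos in design.fixed_positions:
        if window10[pos] != wild[pos]:
            raise WindowMismatchError(
                f"window {window10!r} differs from design at fixed position "
                f"{pos} ({window10[pos]} != {wild[pos]})")
    return "".join(window10[p] for p in design.degenerate_positions)


def enumerate_variants(design: LibraryDesign) -> list[VariantSequence]:
    """All 4^k variants of a design, in lexicographic key order."""
    variants = []
    for bases in itertools.product(ALPHABET, repeat=design.key_length):
        key = "".join(bases)
        variants.append(VariantSequence(
            library=design.name, key=key,
            window10=window_from_key(design, key)))
    return variants


def is_valid_barcode(barcode: str) -> bool:
    """True iff ``barcode`` matches VNNVNNVNNVNN (V in {A,C,G})."""
    if len(barcode) != BARCODE_LENGTH or set(barcode) - set(ALPHABET):
        return False
    return all(barcode[i] != "T" for i in BARCODE_V_POSITIONS)


def validate_barcode(barcode: str) -> str:
    if not is_valid_barcode(barcode):
        raise BarcodePatternError(
            f"barcode {barcode!r} does not match VNNVNNVNNVNN")
    return barcode


@dataclass(frozen=True)
class ConstructTemplate:
    """Segment layout of the reporter construct.

    Order: variant-bearing 50-bp promoter fragment, 35S minimal promoter,
    synJ 5' UTR, ATG, 12-bp barcode slot, reporter ORF prefix.  The
    transcript begins within the minimal promoter, so RNA reads carry the
    barcode between the synJ/ATG junction and the reporter prefix.
    """

    min35s: str = MIN35S_SYNTHETIC
    synj: str = SYNJ
    reporter_prefix: str = REPORTER_PREFIX_SYNTHETIC

    def __post_init__(self):
        if len(self.synj) != 28:
            raise DesignError("synJ segment must be the 28-mer 5' UTR")

    @property
    def fixed_spacer(self) -> str:
        """Fixed sequence between promoter fragment and barcode."""
        return self.min35s + self.synj + "ATG"

    @property
    def barcode_offset(self) -> int:
        """Offset of the barcode slot relative to the promoter start."""
        return 50 + len(self.fixed_spacer)

    @property
    def total_length(self) -> int:
        return self.barcode_offset + BARCODE_LENGTH + len(self.reporter_prefix)

    # anchors used by RNA barcode extraction
    @property
    def rna_anchor5(self) -> str:
        return self.synj[-8:] + "ATG"

    @property
    def rna_anchor3(self) -> str:
        return self.reporter_prefix[:10]


DEFAULT_TEMPLATE = ConstructTemplate()


def assemble_construct(variant: VariantSequence, barcode: str,
                       design: LibraryDesign,
                       template: ConstructTemplate = DEFAULT_TEMPLATE) -> str:
    """Concatenate the full reporter construct for a (variant, barcode) pair.

    The 50-bp promoter segment equals the design context with the variant's
    window substituted; a wild-type variant reproduces the context exactly.
    """
    validate_barcode(barcode)
    if variant.library != design.name:
        raise DesignError(
            f"variant from library {variant.library!r} assembled against "
            f"design {design.name!r}")
    # re-derive the window from the key so inconsistent VariantSequence
    # objects are caught here rather than downstream
    window = window_from_key(design, variant.key)
    if window != variant.window10:
        raise DesignError("variant window10 inconsistent with its key")
    promoter = (design.context[:design.window_start] + window
                + design.context[design.window_end:])
    return promoter + template.fixed_spacer + barcode + template.reporter_prefix
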