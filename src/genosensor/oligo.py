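"""Oligonucleotide duplex model: position-wise complementarity of probe/target pairs.

Probes are stored 5'->3' and targets 3'->5' exactly as supplied, so a duplex
is scanned index-by-index without reversing either strand.  The character
``-`` marks an explicitly unpaired position (insertion/deletion placeholder)
and never base-pairs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

ALPHABET = frozenset("ACGT-")
GAP = "-"

#: Watson-Crick complement lookup (probe base -> complementary target base).
WC_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class PairState(str, enum.Enum):
    """State of one aligned duplex position."""

    WATSON_CRICK_MATCH = "watson_crick_match"
    MISMATCH = "mismatch"
    GAP_OPPOSITE_BASE = "gap_opposite_base"
    GAP_OPPOSITE_GAP = "gap_opposite_gap"


class DuplexClass(str, enum.Enum):
    """Coarse structural class of a probe/target duplex."""

    FULL_COMPLEMENT = "full_complement"
    POINT_MISMATCH = "point_mismatch"
    BULGE_OR_LOOP = "bulge_or_loop"
    MULTI_DEFECT = "multi_defect"


class OligoValidationError(ValueError):
    """Raised when an oligo sequence violates the alphabet or role contract."""


class AlignmentLengthError(ValueError):
    """Raised when probe and target padded lengths differ."""


@dataclass(frozen=True)
class Oligo:
    """A single synthetic DNA strand.

    Parameters
    ----------
    id : str
        Identifier, e.g. ``probe_DNA_1``.
    sequence : str
        Bases over ``{A, C, G, T, -}``; probes are written 5'->3', targets
        3'->5' (``orientation`` records which).
    role : {'probe', 'target'}
    orientation : {'5to3', '3to5'}
    thiol_modified : bool
        Whether the strand carries a 5' thiol-C6 linker (metadata only; the
        linker is not part of ``sequence``).
    variant_label : str
        Mutation panel this strand belongs to, e.g. ``5382insC``.
    mutation_bearing : bool
        Whether the strand carries the variant allele.
    """

    id: str
    sequence: str
    role: str
    orientation: str = "5to3"
    thiol_modified: bool = False
    variant_label: str = ""
    mutation_bearing: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise OligoValidationError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise OligoValidationError(
                f"{self.id}: characters {sorted(bad)} outside alphabet ACGT-"
            )
        if self.role not in ("probe", "target"):
            raise OligoValidationError(f"{self.id}: role must be probe|target")
        if self.orientation not in ("5to3", "3to5"):
            raise OligoValidationError(f"{self.id}: orientation must be 5to3|3to5")
        # the thiol linker sits at the 5' terminus; a gap placeholder there
        # would put the linker on a non-existent base
        if self.thiol_modified and self.sequence[0] == GAP:
            raise OligoValidationError(
                f"{self.id}: gap placeholder at the thiol linker position"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DuplexAlignment:
    """Position-wise pairing of one probe against one target."""

    probe_id: str
    target_id: str
    pair_states: tuple[PairState, ...]
    n_match: int = field(init=False)
    n_mismatch: int = field(init=False)
    n_gap: int = field(init=False)

    def __post_init__(self) -> None:
        counts = {state: 0 for state in PairState}
        for s in self.pair_states:
            counts[s] += 1
        object.__setattr__(self, "n_match", counts[PairState.WATSON_CRICK_MATCH])
        object.__setattr__(self, "n_mismatch", counts[PairState.MISMATCH])
        object.__setattr__(
            self,
            "n_gap",
            counts[PairState.GAP_OPPOSITE_BASE] + counts[PairState.GAP_OPPOSITE_GAP],
        )

    @property
    def n_gap_opposite_base(self) -> int:
        return sum(1 for s in self.pair_states if s is PairState.GAP_OPPOSITE_BASE)

    @property
    def n_gap_opposite_gap(self) -> int:
        return sum(1 for s in self.pair_states if s is PairState.GAP_OPPOSITE_GAP)

    @property
    def fully_complementary(self) -> bool:
        return self.n_mismatch == 0 and self.n_gap_opposite_base == 0

    def __len__(self) -> int:
        return len(self.pair_states)


def pair_positions(probe: Oligo, target: Oligo) -> DuplexAlignment:
    """Scan a probe (5'->3') against a target (3'->5') position by position.

    Both strands must have equal padded length; gap placeholders are kept in
    register, so no alignment algorithm runs here.

    Raises
    ------
    AlignmentLengthError
        If padded lengths differ.
    OligoValidationError
        If roles are swapped.
    """
    if probe.role != "probe" or target.role != "target":
        raise OligoValidationError(
            f"expected (probe, target), got ({probe.role}, {target.role})"
        )
    if len(probe) != len(target):
        raise AlignmentLengthError(
            f"{probe.id} ({len(probe)} nt) vs {target.id} ({len(target)} nt): "
            "padded lengths differ"
        )
    states = []
    for p, t in zip(probe.sequence, target.sequence):
        if p == GAP and t == GAP:
            states.append(PairState.GAP_OPPOSITE_GAP)
        elif p == GAP or t == GAP:
            states.append(PairState.GAP_OPPOSITE_BASE)
        elif WC_COMPLEMENT[p] == t:
            states.append(PairState.WATSON_CRICK_MATCH)
        else:
            states.append(PairState.MISMATCH)
    return DuplexAlignment(probe.id, target.id, tuple(states))


def classify_duplex(alignment: DuplexAlignment) -> DuplexClass:
    """Map an alignment to its structural class.

    ``full_complement`` iff no mismatches and no gap-opposite-base positions;
    ``point_mismatch`` iff exactly one mismatch and no gaps opposite bases;
    ``bulge_or_loop`` iff >= 1 gap opposite a base and no mismatches;
    ``multi_defect`` otherwise.
    """
    if alignment.fully_complementary:
        return DuplexClass.FULL_COMPLEMENT
    if alignment.n_mismatch == 1 and alignment.n_gap_opposite_base == 0:
        return DuplexClass.POINT_MISMATCH
    if alignment.n_mismatch == 0 and alignment.n_gap_opposite_base >= 1:
        return DuplexClass.BULGE_OR_LOOP
    return DuplexClass.MULTI_DEFECT
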