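"""Packaged reference tables: oligo panel, primers, kinetic constants, outcomes.

Every loader verifies the file against a SHA-256 manifest
(``data/checksums.json``) before parsing, so silent fixture corruption
surfaces as :class:`DataIntegrityError` rather than wrong numbers.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd
from Bio import SeqIO

from .oligo import Oligo

__all__ = [
    "DataIntegrityError",
    "load_oligos",
    "load_primers",
    "load_kinetics_table",
    "load_outcome_table",
    "PANELS",
]

#: The five mutation panels, in table order.
PANELS = ("5370C>T", "5382insC", "c.4035delA", "185delAG", "3819del5GTAAA")


class DataIntegrityError(RuntimeError):
    """Raised when a packaged fixture fails its checksum."""


def _data_root():
    return resources.files("genosensor") / "data"


def _checked_path(name: str):
    path = _data_root() / name
    manifest = json.loads((_data_root() / "checksums.json").read_text())
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if manifest.get(name) != digest:
        raise DataIntegrityError(
            f"{name}: checksum {digest} does not match manifest entry {manifest.get(name)}"
        )
    return path


def load_oligos() -> dict[str, Oligo]:
    """All 20 probe/target strands keyed by id (``probe_DNA_1`` ...)."""
    path = _checked_path("table1_oligos.fasta")
    oligos: dict[str, Oligo] = {}
    with path.open() as handle:
        for record in SeqIO.parse(handle, "fasta"):
            attrs = dict(
                token.split("=", 1) for token in record.description.split()[1:]
            )
            oligos[record.id] = Oligo(
                id=record.id,
                sequence=str(record.seq),
                role=attrs["role"],
                orientation={"5to3": "5to3", "3to5": "3to5"}[attrs["orientation"]],
                thiol_modified=attrs["thiol"] == "true",
                variant_label=attrs["variant"],
                mutation_bearing=attrs["mutation_bearing"] == "true",
            )
    return oligos


def oligo_pairs() -> list[tuple[Oligo, Oligo]]:
    """Same-index (probe_i, target_i) pairs, i = 1..10."""
    oligos = load_oligos()
    return [
        (oligos[f"probe_DNA_{i}"], oligos[f"target_DNA_{i}"]) for i in range(1, 11)
    ]


def load_primers() -> pd.DataFrame:
    """PCR primer table (data fixture only; no primer computation here)."""
    with _checked_path("table2_primers.csv").open() as handle:
        return pd.read_csv(handle)


def load_kinetics_table() -> pd.DataFrame:
    """Per-panel kinetic constants for synthetic targets and patient samples.

    Columns: panel, row_label, mutation_status, then ka/kd/Kd/Ka for the
    wild-type-probe and mutant-probe interactions.
    """
    with _checked_path("table3_kinetics.csv").open() as handle:
        return pd.read_csv(handle)


def load_outcome_table() -> pd.DataFrame:
    """Per-sample genotyping outcomes for QCM-D, SPR and PCR (as printed)."""
    with _checked_path("table4_calls.csv").open() as handle:
        return pd.read_csv(handle)
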