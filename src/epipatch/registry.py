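"""Eplet registry records and per-antigen eplet residue lookup.

An *eplet* is a small set of polymorphic residues on an HLA chain that
forms the functional core of a B-cell epitope.  A registry record names
the eplet (position of its first residue plus the residue codes, e.g.
``40ERV`` for E40/R41/V45), says which chain it sits on, whether it is
antibody-verified, and which antigens carry it.

Registry files use a simple CSV dialect::

    eplet,chain,positions,aas,verified,antigens
    40ERV,A,40;41;45,E;R;V,True,AG001;AG003

Positions refer to a per-locus reference numbering.  For alleles whose
sequence carries insertions or deletions relative to that reference, a
:class:`PositionMap` built from a gap-aware pairwise alignment
translates reference positions to allele positions, so homologous
patches are pooled across indel-shifted alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class EpletRecord:
    """One registry entry; composite iff it has more than one residue."""

    name: str
    chain: str
    residues: tuple[tuple[int, str], ...]
    verified: bool

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"eplet {self.name!r} has no residues")

    @property
    def composite(self) -> bool:
        return len(self.residues) > 1


@dataclass
class EpletRegistry:
    """Eplet records plus the per-antigen presence map."""

    records: list[EpletRecord]
    presence: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_name = {r.name: r for r in self.records}

    def record(self, name: str) -> EpletRecord:
        return self._by_name[name]

    def eplets_of(self, antigen_id: str) -> list[EpletRecord]:
        return [self._by_name[n] for n in sorted(self.presence.get(antigen_id, ()))]

    def antigens_carrying(self, name: str) -> list[str]:
        return sorted(a for a, names in self.presence.items() if name in names)

    def residue_sets(
        self, antigen_id: str, position_map: "PositionMap | None" = None
    ) -> tuple[set[tuple[str, int]], set[tuple[str, int]]]:
        """(any-eplet, verified-eplet) residue position sets for one antigen.

        Positions are translated through ``position_map`` when given
        (identity otherwise); reference positions deleted in the allele
        are dropped.
        """
        any_pos: set[tuple[str, int]] = set()
        verified_pos: set[tuple[str, int]] = set()
        for rec in self.eplets_of(antigen_id):
            for pos, _aa in rec.residues:
                mapped = (
                    position_map.translate(rec.chain, pos)
                    if position_map is not None
                    else pos
                )
                if mapped is None:
                    continue
                any_pos.add((rec.chain, mapped))
                if rec.verified:
                    verified_pos.add((rec.chain, mapped))
        return any_pos, verified_pos


def read_registry(path: str | Path) -> EpletRegistry:
    """Read a registry CSV (dialect documented in the module docstring)."""
    import pandas as pd

    df = pd.read_csv(path, dtype=str).fillna("")
    records: list[EpletRecord] = []
    presence: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        positions = [int(p) for p in str(row["positions"]).split(";") if p]
        aas = [a for a in str(row["aas"]).split(";") if a]
        if len(positions) != len(aas):
            raise ValueError(
                f"eplet {row['eplet']!r}: {len(positions)} positions but {len(aas)} residues"
            )
        rec = EpletRecord(
            name=str(row["eplet"]),
            chain=str(row["chain"]),
            residues=tuple(zip(positions, aas)),
            verified=str(row["verified"]).strip().lower() in {"true", "1", "yes"},
        )
        records.append(rec)
        for antigen in str(row["antigens"]).split(";"):
            if antigen:
                presence.setdefault(antigen, set()).add(rec.name)
    return EpletRegistry(records, presence)


def write_registry(registry: EpletRegistry, path: str | Path) -> None:
    import pandas as pd

    rows = []
    for rec in registry.records:
        rows.append(
            {
                "eplet": rec.name,
                "chain": rec.chain,
                "positions": ";".join(str(p) for p, _ in rec.residues),
                "aas": ";".join(a for _, a in rec.residues),
                "verified": rec.verified,
                "antigens": ";".join(registry.antigens_carrying(rec.name)),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class PositionMap:
    """Translation from reference numbering to allele numbering per chain."""

    mapping: dict[tuple[str, int], int]

    def translate(self, chain: str, position: int) -> int | None:
        return self.mapping.get((chain, position))


def build_position_map(
    reference: dict[str, str], allele: dict[str, str]
) -> PositionMap:
    """Gap-aware mapping of reference positions onto an allele's numbering.

    Chains present in both sequence dictionaries are globally aligned;
    reference positions aligned to a gap (deleted in the allele) have no
    image and translate to ``None``.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=2.0,
        mismatch_score=-1.0,
        open_gap_score=-4.0,
        extend_gap_score=-0.5,
    )
    mapping: dict[tuple[str, int], int] = {}
    for chain, ref_seq in reference.items():
        if chain not in allele:
            continue
        aln = aligner.align(ref_seq, allele[chain])[0]
        for (r0, r1), (a0, a1) in zip(*aln.aligned):
            for off in range(r1 - r0):
                mapping[(chain, r0 + off + 1)] = a0 + off + 1
    return PositionMap(mapping)
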