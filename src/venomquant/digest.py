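"""In silico tryptic digestion, peptide matching and protein inference.

Peptide identity is assumed already established upstream (the matching here
is exact substring search against the transcriptome-derived database, with
isoleucine and leucine folded together by default because they are
mass-indistinguishable in bottom-up MS).  Proteoform redundancy in the
database is collapsed by mature-sequence identity, tolerating a single
internal insertion such as an untranslated stretch retained in one
assembly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .records import AA_ALPHABET, InputError, ParameterError, ToxinRecord

#: cleave C-terminal to K or R, except when followed by P
TRYPSIN_RULE = r"[KR](?!P)"


def tryptic_digest(sequence: str, max_missed_cleavages: int = 0) -> list:
    """Tryptic peptides of ``sequence`` with up to the given missed cleavages.

    Returns ``(peptide, start, end, missed_cleavages)`` tuples with 0-based
    half-open coordinates, ordered by position then length.  Fully cleaved
    peptides (0 missed) concatenate back to the input sequence.
    """
    if not sequence:
        raise InputError("empty sequence")
    bad = set(sequence) - set(AA_ALPHABET)
    if bad:
        raise InputError(f"illegal residue letters {sorted(bad)}")
    if max_missed_cleavages < 0:
        raise ParameterError("max_missed_cleavages must be >= 0")

    # cleavage site positions (index after which the backbone is cut)
    cut_after = [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    boundaries = [0] + [i + 1 for i in cut_after] + [len(sequence)]
    out = []
    for a, b in itertools.combinations(range(len(boundaries)), 2):
        missed = b - a - 1
        if missed > max_missed_cleavages:
            continue
        start, end = boundaries[a], boundaries[b]
        out.append((sequence[start:end], start, end, missed))
    out.sort(key=lambda p: (p[1], p[2]))
    return out


def _fold_il(seq: str) -> str:
    return seq.replace("I", "L")


@dataclass(frozen=True)
class PeptideMatch:
    peptide: str
    protein_id: str
    start: int
    end: int
    unique: bool


def match_peptides(
    peptides,
    database,
    il_equivalent: bool = True,
    groups: dict | None = None,
) -> list:
    """Exact-substring matches of peptides against precursor sequences.

    With ``il_equivalent`` (default), I and L are treated as the same
    residue on both sides.  ``groups`` optionally maps protein id to a
    collapsed proteoform-group id; a peptide is *unique* when all its
    matches fall in a single group (or a single protein when no grouping is
    given).  Returns :class:`PeptideMatch` objects; match order is
    independent of database order.
    """
    if not database:
        raise InputError("empty database")
    grp = groups or {r.id: r.id for r in database}
    folded = {
        r.id: (_fold_il(r.precursor) if il_equivalent else r.precursor)
        for r in database
    }
    matches = []
    for pep in peptides:
        q = _fold_il(pep) if il_equivalent else pep
        hits = []
        for rec in database:
            hay = folded[rec.id]
            pos = hay.find(q)
            while pos != -1:
                hits.append((rec.id, pos, pos + len(pep)))
                pos = hay.find(q, pos + 1)
        unique = len({grp.get(pid, pid) for pid, _, _ in hits}) == 1
        for pid, s, e in hits:
            matches.append(PeptideMatch(pep, pid, s, e, unique))
    matches.sort(key=lambda m: (m.peptide, m.protein_id, m.start))
    return matches


def infer_proteins(matches, min_unique_peptides: int = 1) -> list:
    """Protein ids with at least ``min_unique_peptides`` unique peptides."""
    if min_unique_peptides < 1:
        raise ParameterError("min_unique_peptides must be >= 1")
    uniques: dict[str, set] = {}
    for m in matches:
        if m.unique:
            uniques.setdefault(m.protein_id, set()).add(m.peptide)
    return sorted(
        pid for pid, peps in uniques.items() if len(peps) >= min_unique_peptides
    )


def coverage(matches, record: ToxinRecord) -> float:
    """Fraction of the protein's residues covered by its matches."""
    intervals = sorted(
        (m.start, m.end) for m in matches if m.protein_id == record.id
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in intervals:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / len(record.precursor)


# --- proteoform collapsing ------------------------------------------------


def _identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    return aligner


def _groupable(
    a: str, b: str, threshold: float, max_internal_insertion: int,
    aligner: Align.PairwiseAligner,
) -> bool:
    """Identity >= threshold on mature chains, allowing internal gap runs of
    at most ``max_internal_insertion`` residues."""
    if not a or not b:
        return False
    aln = aligner.align(a, b)[0]
    identity = aln.score / min(len(a), len(b))
    if identity < threshold:
        return False
    # gaps between consecutive aligned blocks are internal by construction;
    # terminal length differences do not enter here
    for blocks in aln.aligned:
        for (_s0, e0), (s1, _e1) in zip(blocks, blocks[1:]):
            if s1 - e0 > max_internal_insertion:
                return False
    return True


@dataclass(frozen=True)
class ProteoformGroup:
    representative: str
    members: tuple


def collapse_proteoforms(
    records,
    identity_threshold: float = 0.95,
    max_internal_insertion: int = 50,
) -> list:
    """Collapse redundant proteoform records into groups.

    Two records of the same family group together when their mature chains
    reach ``identity_threshold`` global identity (matches divided by the
    shorter mature length, counted under a gap-free-scoring global
    alignment) after tolerating internal insertions of up to
    ``max_internal_insertion`` residues present in one record only — e.g.
    assemblies differing solely in the precursor region, or one carrying a
    retained untranslated stretch mid-sequence.  Groups are single-linkage
    closures; the representative is the longest mature sequence (ties:
    lexicographically smallest id).
    """
    if not 0 < identity_threshold <= 1:
        raise ParameterError("identity_threshold must be in (0, 1]")
    records = list(records)
    aligner = _identity_aligner()
    parent = {r.id: r.id for r in records}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for r1, r2 in itertools.combinations(records, 2):
        if r1.family != r2.family:
            continue
        if _groupable(
            r1.mature, r2.mature, identity_threshold, max_internal_insertion,
            aligner,
        ):
            parent[find(r1.id)] = find(r2.id)

    by_root: dict[str, list] = {}
    by_id = {r.id: r for r in records}
    for r in records:
        by_root.setdefault(find(r.id), []).append(r.id)
    groups = []
    for ids in by_root.values():
        rep = min(ids, key=lambda i: (-len(by_id[i].mature), i))
        groups.append(ProteoformGroup(representative=rep, members=tuple(sorted(ids))))
    groups.sort(key=lambda g: g.representative)
    return groups


def group_map(groups) -> dict:
    """Map member id → representative id for a list of groups."""
    return {m: g.representative for g in groups for m in g.members}


def read_database(fasta_path, annotations_path) -> list:
    """Read a protein FASTA plus its annotation sidecar into ToxinRecords."""
    from Bio import SeqIO

    ann = pd.read_csv(annotations_path, sep="\t").set_index("id")
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in ann.index:
            raise InputError(f"no annotation row for sequence {rec.id!r}")
        row = ann.loc[rec.id]
        records.append(
            ToxinRecord(
                id=rec.id,
                family=str(row["family"]),
                precursor=str(rec.seq),
                mature_start=int(row["mature_start"]),
                mass_kda=float(row["mass_kda"]),
            )
        )
    return records
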