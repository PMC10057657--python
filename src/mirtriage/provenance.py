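"""Species-of-origin calls for xenograft proteomics identifications.

Proteins identified in a patient-derived xenograft may derive from the
engrafted human tumor cells or from infiltrating mouse stroma. Each
identifying peptide is searched verbatim against the human and mouse
proteome databases; a protein with at least one human-unique peptide
and no mouse-unique peptide is called human-not-murine, the mirror
case murine-not-human, and everything else (all peptides shared, or
conflicting species-unique evidence) is ambiguous. No enzymatic digest
or mass tolerance is modelled: classification is by exact substring
scrutiny of the already-identified peptides.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Mapping

from Bio import SeqIO

from .io import OriginCall, PeptideEvidence, ProteinDEEntry

ORIGINS = ("human_only", "mouse_only", "shared", "unmatched")


def _load_db(db) -> dict[str, str]:
    if isinstance(db, Mapping):
        seqs = {str(k): str(v).upper() for k, v in db.items()}
    else:
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(Path(db)), "fasta")
        }
    if not seqs:
        raise ValueError(f"empty protein database: {db!r}")
    return seqs


def _haystack(seqs: dict[str, str], merge_il: bool) -> str:
    joined = "\x00".join(seqs[k] for k in sorted(seqs))
    return joined.replace("L", "I") if merge_il else joined


def classify_peptides(
    evidence: list[PeptideEvidence],
    human_db,
    mouse_db,
    merge_il: bool = False,
) -> dict[PeptideEvidence, str]:
    """Assign each peptide an origin in {human_only, mouse_only, shared,
    unmatched} by exact substring presence in the two databases.

    ``human_db`` / ``mouse_db`` are FASTA paths or id->sequence
    mappings. ``merge_il=True`` folds leucine onto isoleucine before
    matching (the two are isobaric in mass spectrometry); the default
    keeps them distinct.
    """
    human = _haystack(_load_db(human_db), merge_il)
    mouse = _haystack(_load_db(mouse_db), merge_il)
    calls: dict[PeptideEvidence, str] = {}
    for ev in evidence:
        pep = ev.peptide_sequence.replace("L", "I") if merge_il else ev.peptide_sequence
        in_h = pep in human
        in_m = pep in mouse
        if in_h and in_m:
            calls[ev] = "shared"
        elif in_h:
            calls[ev] = "human_only"
        elif in_m:
            calls[ev] = "mouse_only"
        else:
            calls[ev] = "unmatched"
    return calls


def call_protein_origin(peptide_calls: dict[PeptideEvidence, str]) -> list[OriginCall]:
    """Aggregate per-peptide origins into one category per protein.

    >=1 human-unique and 0 mouse-unique peptides -> human_not_murine;
    the mirror case -> murine_not_human; otherwise ambiguous (covers
    both the all-shared case and conflicting species-unique evidence).
    A protein whose peptides are all unmatched is an error. Unmatched
    peptides are otherwise ignored.
    """
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for ev, origin in peptide_calls.items():
        counts[ev.protein_id][origin] += 1
    out = []
    for pid in sorted(counts):
        c = counts[pid]
        n_h, n_m, n_s = c["human_only"], c["mouse_only"], c["shared"]
        if n_h + n_m + n_s == 0:
            raise ValueError(
                f"protein {pid!r}: no peptide matched either database"
            )
        if n_h >= 1 and n_m == 0:
            cat = "human_not_murine"
        elif n_m >= 1 and n_h == 0:
            cat = "murine_not_human"
        else:
            cat = "ambiguous"
        out.append(
            OriginCall(
                protein_id=pid,
                category=cat,
                n_human_only=n_h,
                n_mouse_only=n_m,
                n_shared=n_s,
            )
        )
    return out


def filter_human_proteins(
    protein_de: list[ProteinDEEntry],
    origin_calls: list[OriginCall],
) -> list[ProteinDEEntry]:
    """Restrict xenograft-contrast protein entries to confidently human
    proteins. Entries in the F1vT comparison are kept only when their
    gene has a human_not_murine origin call; tumor/normal entries (all
    human tissue) pass through unchanged."""
    human = {c.protein_id for c in origin_calls if c.category == "human_not_murine"}
    return [
        e for e in protein_de if e.comparison != "F1vT" or e.gene_symbol in human
    ]
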