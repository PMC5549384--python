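"""Protein-change parsing and residue-group variation statistics.

The twenty standard residues are partitioned into four physicochemical
groups — hydrophobic (A, V, L, I, M, F, W, P), polar (G, S, T, C, Y, N, Q,
H), acidic (E, D) and basic (K, R) — and substitutions are tallied as
exchanges between groups, alongside per-residue gain/loss counts and
insertion/deletion spectra.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1

GROUPS = ("hydrophobic", "polar", "acidic", "basic")

GROUP_OF = {
    **{aa: "hydrophobic" for aa in "AVLIMFWP"},
    **{aa: "polar" for aa in "GSTCYNQH"},
    **{aa: "acidic" for aa in "ED"},
    **{aa: "basic" for aa in "KR"},
}

CHANGE_KINDS = (
    "substitution",
    "synonymous",
    "insertion",
    "deletion",
    "frameshift",
    "stop_gained",
    "stop_lost",
)

_3TO1 = {k.capitalize(): v for k, v in protein_letters_3to1.items()}
_3TO1["Ter"] = "*"
_1TO3 = dict(protein_letters_1to3)
_1TO3["*"] = "Ter"


class ProteinChangeParseError(ValueError):
    pass


def aa_group(aa: str) -> str:
    """Physicochemical group of a standard residue (1- or 3-letter code)."""
    one = normalize_residue(aa)
    try:
        return GROUP_OF[one]
    except KeyError:
        raise ValueError(f"residue {aa!r} has no physicochemical group") from None


def normalize_residue(aa: str) -> str:
    """Accept 1-letter or 3-letter codes; return the 1-letter code."""
    if len(aa) == 1:
        return aa.upper()
    try:
        return _3TO1[aa.capitalize()]
    except KeyError:
        raise ValueError(f"unknown residue code {aa!r}") from None


def to_three_letter(aa: str) -> str:
    return _1TO3[normalize_residue(aa)]


@dataclass
class ProteinChange:
    """One protein-level change, e.g. parsed from an HGVS.p-style string."""

    position: int
    ref_res: str
    alt_res: str
    kind: str
    inserted_res: str = ""
    deleted_res: str = ""

    def __post_init__(self) -> None:
        if self.kind not in CHANGE_KINDS:
            raise ValueError(f"unknown change kind {self.kind!r}")
        if self.kind in ("substitution", "synonymous"):
            same = self.ref_res == self.alt_res
            if same != (self.kind == "synonymous"):
                raise ValueError("synonymous iff ref_res == alt_res")

    @property
    def inserted_len(self) -> int:
        return len(self.inserted_res)


_AA3 = "|".join(sorted(_3TO1, key=len, reverse=True))
_RES = rf"(?:{_AA3}|[A-Z\*])"
_HEAD = re.compile(rf"^(?P<ref>{_RES})(?P<pos>\d+)(?P<rest>.*)$")
_RES_RUN = re.compile(rf"^(?:{_RES})+$")


def _split_residues(text: str) -> List[str]:
    """Split a run of residue codes ('GluGluLys' or 'EEK') into 1-letter codes."""
    if not _RES_RUN.match(text):
        raise ProteinChangeParseError(f"unparseable residue run {text!r}")
    out = []
    i = 0
    while i < len(text):
        if text[i : i + 3].capitalize() in _3TO1:
            out.append(_3TO1[text[i : i + 3].capitalize()])
            i += 3
        else:
            out.append(normalize_residue(text[i]))
            i += 1
    return out


def parse_protein_change(text: str) -> ProteinChange:
    """Parse an HGVS.p-style short protein-change string.

    Recognized forms (3-letter or 1-letter residue codes):

    - ``Glu10Lys`` — substitution; ``Glu10Glu`` — synonymous
    - ``Arg1024Ter`` / ``Arg1024*`` — stop gained
    - ``Ter110Gln`` — stop lost
    - ``Glu1294Argfs`` (optional ``Ter`` + number suffix) — frameshift
    - ``Glu10del`` / ``Glu10_Asp12del`` — deletion
    - ``Glu10_Lys11insGluGlu`` — insertion of the given residues
    """
    text = text.strip().removeprefix("p.")
    m = _HEAD.match(text)
    if not m:
        raise ProteinChangeParseError(f"unparseable protein change {text!r}")
    ref = normalize_residue(m.group("ref"))
    pos = int(m.group("pos"))
    rest = m.group("rest")

    if rest.startswith("_"):
        m2 = re.match(rf"^_(?P<ref2>{_RES})(?P<pos2>\d+)(?P<op>ins|del)(?P<tail>.*)$", rest)
        if not m2:
            raise ProteinChangeParseError(f"unparseable interval change {text!r}")
        ref2 = normalize_residue(m2.group("ref2"))
        pos2 = int(m2.group("pos2"))
        if m2.group("op") == "ins":
            inserted = "".join(_split_residues(m2.group("tail")))
            return ProteinChange(pos, ref, "", "insertion", inserted_res=inserted)
        if m2.group("tail"):
            raise ProteinChangeParseError(f"trailing token {m2.group('tail')!r} in {text!r}")
        # range deletion: only the endpoint residues are named in the string
        deleted = ref + "?" * max(pos2 - pos - 1, 0) + ref2
        return ProteinChange(pos, ref, "", "deletion", deleted_res=deleted)

    if rest == "del":
        return ProteinChange(pos, ref, "", "deletion", deleted_res=ref)
    fs = re.match(rf"^(?P<alt>{_RES})?fs(?:Ter\d*|\*\d*)?$", rest)
    if fs:
        alt = normalize_residue(fs.group("alt")) if fs.group("alt") else ""
        return ProteinChange(pos, ref, alt, "frameshift")
    if rest in ("Ter", "*"):
        if ref == "*":
            raise ProteinChangeParseError(f"stop-to-stop change {text!r}")
        return ProteinChange(pos, ref, "*", "stop_gained")
    if _RES_RUN.match(rest) and len(_split_residues(rest)) == 1:
        alt = _split_residues(rest)[0]
        if ref == "*":
            return ProteinChange(pos, ref, alt, "stop_lost")
        kind = "synonymous" if alt == ref else "substitution"
        return ProteinChange(pos, ref, alt, kind)
    if rest == "=":
        return ProteinChange(pos, ref, ref, "synonymous")
    raise ProteinChangeParseError(f"unparseable token {rest!r} in {text!r}")


@dataclass
class ExchangeMatrix:
    """4×4 substitution tally between residue groups plus gain/loss vectors.

    ``counts`` rows are the source (lost) group, columns the destination
    (gained) group.  Substitutions involving a stop codon have no group and
    are kept in ``stop_involving`` instead.
    """

    counts: pd.DataFrame
    loss: pd.Series
    gain: pd.Series
    stop_involving: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def row_fractions(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)


def exchange_matrix(changes: Iterable[ProteinChange]) -> ExchangeMatrix:
    """Tally substitutions between residue groups.

    Only records with kind == 'substitution' enter the 4×4 matrix; stop
    gains/losses are counted in the side tally, everything else ignored.
    """
    residues = sorted(GROUP_OF)
    counts = pd.DataFrame(0, index=list(GROUPS), columns=list(GROUPS), dtype=int)
    loss = pd.Series(0, index=residues, dtype=int)
    gain = pd.Series(0, index=residues, dtype=int)
    stop_involving = 0
    for ch in changes:
        if ch.kind in ("stop_gained", "stop_lost"):
            stop_involving += 1
            continue
        if ch.kind != "substitution":
            continue
        if ch.ref_res not in GROUP_OF or ch.alt_res not in GROUP_OF:
            stop_involving += 1
            continue
        counts.loc[GROUP_OF[ch.ref_res], GROUP_OF[ch.alt_res]] += 1
        loss[ch.ref_res] += 1
        gain[ch.alt_res] += 1
    return ExchangeMatrix(counts=counts, loss=loss, gain=gain, stop_involving=stop_involving)


VARIATION_TYPES = ("substitution", "synonymous", "insertion", "deletion")


def variation_type_by_group(changes: Iterable[ProteinChange]) -> pd.DataFrame:
    """4-group × 4-type contingency table of residue-level variation.

    Substitutions and synonymous changes count once under the affected
    residue's group; insertions and deletions are attributed per
    inserted/deleted residue.  Suitable as chi-square input.
    """
    table = pd.DataFrame(0, index=list(GROUPS), columns=list(VARIATION_TYPES), dtype=int)
    for ch in changes:
        if ch.kind in ("substitution", "synonymous"):
            if ch.ref_res in GROUP_OF:
                table.loc[GROUP_OF[ch.ref_res], ch.kind] += 1
        elif ch.kind == "insertion":
            for aa in ch.inserted_res:
                if aa in GROUP_OF:
                    table.loc[GROUP_OF[aa], "insertion"] += 1
        elif ch.kind == "deletion":
            for aa in ch.deleted_res or ch.ref_res:
                if aa in GROUP_OF:
                    table.loc[GROUP_OF[aa], "deletion"] += 1
    return table


def insertion_spectrum(changes: Iterable[ProteinChange], max_len: int = 12) -> pd.DataFrame:
    """Counts of insertions by inserted length (1..max_len, longer pooled).

    Rows are lengths; columns are the four groups plus a ``total`` column.
    Group columns count inserted residues, the total column counts
    insertion events of that length.
    """
    idx = list(range(1, max_len + 1))
    spec = pd.DataFrame(0, index=idx, columns=list(GROUPS) + ["total"], dtype=int)
    for ch in changes:
        if ch.kind != "insertion" or ch.inserted_len == 0:
            continue
        length = min(ch.inserted_len, max_len)
        spec.loc[length, "total"] += 1
        for aa in ch.inserted_res:
            if aa in GROUP_OF:
                spec.loc[length, GROUP_OF[aa]] += 1
    return spec


def affected_residue_counts(changes: Iterable[ProteinChange]) -> pd.Series:
    """Per-residue counts of being mutated (substituted, synonymous or deleted).

    Insertions do not alter an existing residue and are excluded.
    """
    counter: Counter = Counter()
    for ch in changes:
        if ch.kind in ("substitution", "synonymous"):
            counter[ch.ref_res] += 1
        elif ch.kind == "deletion":
            for aa in ch.deleted_res or ch.ref_res:
                if aa in GROUP_OF:
                    counter[aa] += 1
    return pd.Series(counter, dtype=int).reindex(sorted(GROUP_OF), fill_value=0)


def kind_counts(changes: Iterable[ProteinChange]) -> pd.Series:
    tally = Counter(ch.kind for ch in changes)
    return pd.Series(tally, dtype=int).reindex(list(CHANGE_KINDS), fill_value=0)
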