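"""HLA allele nomenclature and the aligned peptide-binding-domain store.

Allele names follow standard HLA nomenclature ("HLA-A*02:01", "DQB1*03",
"B*44:02N").  Six loci are supported: the class I loci A, B, C (store
sequences are exon 2+3 translations) and the class II loci DRB1, DQB1,
DPB1 (exon 2 translations).  The store is read from a FASTA file whose
headers are a single allele-name token, optionally followed by
"class=I|II"; all sequences at one locus must share one alignment length.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from difflib import get_close_matches
from pathlib import Path

from Bio import SeqIO

from .grantham import GAP_CHARS, STANDARD_RESIDUES

logger = logging.getLogger(__name__)

CLASS_I_LOCI = ("A", "B", "C")
CLASS_II_LOCI = ("DRB1", "DQB1", "DPB1")
LOCI = CLASS_I_LOCI + CLASS_II_LOCI

#: HLA class per locus (class I uses exons 2+3, class II exon 2).
LOCUS_CLASS = {**{l: "I" for l in CLASS_I_LOCI}, **{l: "II" for l in CLASS_II_LOCI}}

EXPRESSION_SUFFIXES = "NLSCAQ"
_NAME_RE = re.compile(
    r"^(?:HLA-)?(?P<locus>[A-Z0-9]+)\*(?P<fields>[0-9:]+)"
    r"(?P<suffix>[A-Z]?)$",
    re.IGNORECASE,
)

VALID_SEQ_CHARS = frozenset(STANDARD_RESIDUES) | GAP_CHARS


class AlleleError(ValueError):
    pass


class AlleleParseError(AlleleError):
    pass


class AlleleLookupError(AlleleError, KeyError):
    pass


@dataclass(frozen=True, order=True)
class AlleleName:
    """Parsed HLA allele name at 1- or 2-field resolution."""

    locus: str
    field1: str
    field2: str | None = None
    expression_suffix: str | None = None

    @property
    def resolution(self) -> int:
        return 2 if self.field2 is not None else 1

    def __str__(self) -> str:
        s = f"{self.locus}*{self.field1}"
        if self.field2 is not None:
            s += f":{self.field2}"
        if self.expression_suffix:
            s += self.expression_suffix
        return s


def parse_allele_name(text: str) -> AlleleName:
    """Parse "A*02:01", "HLA-A*02:01", "DQB1*03" or "B*44:02N".

    The "HLA-" prefix is stripped and the locus is case-insensitive.
    Raises :class:`AlleleParseError` naming the offending position for
    unknown loci, non-numeric fields or >2 fields.
    """
    token = text.strip()
    m = _NAME_RE.match(token)
    if not m:
        if "*" not in token:
            raise AlleleParseError(f"{text!r}: missing '*' separator")
        raise AlleleParseError(f"{text!r}: not a valid allele name")
    locus = m.group("locus").upper()
    if locus not in LOCI:
        raise AlleleParseError(
            f"{text!r}: unknown locus {locus!r} at position 0 "
            f"(supported: {', '.join(LOCI)})"
        )
    fields = m.group("fields").split(":")
    if len(fields) > 2:
        raise AlleleParseError(
            f"{text!r}: more than 2 fields at position {token.index(':')}"
        )
    for f in fields:
        if not f.isdigit():
            raise AlleleParseError(
                f"{text!r}: non-numeric field {f!r} at position {token.index(f or ':')}"
            )
    suffix = m.group("suffix").upper() or None
    if suffix and suffix not in EXPRESSION_SUFFIXES:
        raise AlleleParseError(f"{text!r}: unknown expression suffix {suffix!r}")
    if suffix:
        logger.warning(
            "allele %s carries expression suffix %s; treated as an ordinary sequence",
            token, suffix,
        )
    return AlleleName(locus, fields[0], fields[1] if len(fields) == 2 else None, suffix)


class AlleleStore:
    """Aligned PBD amino-acid sequences keyed by 2-field allele name."""

    def __init__(self) -> None:
        self._records: dict[AlleleName, str] = {}
        self.locus_length: dict[str, int] = {}

    def add(self, name: AlleleName, sequence: str) -> None:
        if name in self._records:
            raise AlleleError(f"duplicate allele {name}")
        bad = set(sequence) - VALID_SEQ_CHARS
        if bad:
            raise AlleleError(
                f"allele {name}: invalid sequence characters {sorted(bad)}"
            )
        expected = self.locus_length.get(name.locus)
        if expected is None:
            self.locus_length[name.locus] = len(sequence)
        elif len(sequence) != expected:
            raise AlleleError(
                f"allele {name}: length {len(sequence)} differs from locus "
                f"{name.locus} alignment length {expected}"
            )
        self._records[name] = sequence

    def __contains__(self, name: AlleleName) -> bool:
        return name in self._records

    def __len__(self) -> int:
        return len(self._records)

    def alleles_at(self, locus: str) -> list[AlleleName]:
        return sorted(n for n in self._records if n.locus == locus)

    def sequence(self, name: AlleleName) -> str:
        try:
            return self._records[name]
        except KeyError:
            near = get_close_matches(
                str(name), [str(n) for n in self._records], n=3, cutoff=0.4
            )
            hint = f"; nearest: {', '.join(near)}" if near else ""
            raise AlleleLookupError(f"allele {name} not in store{hint}") from None


def load_allele_store(path: str | Path) -> AlleleStore:
    """Read an allele store from FASTA (header = one allele-name token).

    Rejects duplicate alleles and ragged per-locus alignments, naming the
    offending allele.
    """
    store = AlleleStore()
    path = Path(path)
    for record in SeqIO.parse(str(path), "fasta"):
        name = parse_allele_name(record.id.split()[0])
        if name.resolution != 2:
            raise AlleleError(f"store entries must be 2-field, got {name}")
        store.add(name, str(record.seq).upper())
    return store


def resolve_sequence(
    name: AlleleName,
    store: AlleleStore,
    policy: str = "smallest",
    frequencies: dict[AlleleName, float] | None = None,
) -> tuple[str, bool]:
    """Return the aligned PBD sequence for an allele name.

    2-field names resolve by exact lookup.  1-field names are expanded to a
    representative 2-field allele of the same allele group present in the
    store: under the default ``"smallest"`` policy the numerically smallest
    field2, under ``"frequency"`` the highest-frequency member per the
    supplied table.  Returns ``(sequence, expanded)`` where ``expanded``
    flags 1-field expansion (provenance).
    """
    if name.resolution == 2:
        return store.sequence(name), False
    group = [
        n for n in store.alleles_at(name.locus)
        if n.field1 == name.field1 and n.field2 is not None
    ]
    if not group:
        candidates = [str(n) for n in store.alleles_at(name.locus)][:5]
        raise AlleleLookupError(
            f"no 2-field allele in group {name} in store; "
            f"known at locus: {', '.join(candidates) or 'none'}"
        )
    if policy == "smallest":
        chosen = min(group, key=lambda n: int(n.field2))
    elif policy == "frequency":
        if frequencies is None:
            raise AlleleError("frequency policy requires a frequency table")
        # deterministic tie-break on the name itself
        chosen = max(group, key=lambda n: (frequencies.get(n, 0.0), str(n)))
    else:
        raise AlleleError(f"unknown resolution policy {policy!r}")
    logger.info("expanded 1-field %s to %s (%s policy)", name, chosen, policy)
    return store.sequence(chosen), True
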