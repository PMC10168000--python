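"""Identifier pattern registry and seeded synthetic corpus generation.

Biological databases assign accession-like identifiers whose surface forms
follow database-specific conventions (``ENSG`` + 11 digits for Ensembl genes,
``CHEMBL`` + digits for ChEMBL, ...).  This module holds one anchored regular
expression per database, matches query strings against the whole collection,
and samples synthetic identifier corpora from structured generator templates
so that models can be trained and evaluated without live database access.

The built-in registry emulates 39 Ensembl-linked databases.  Its templates
are plausible reconstructions of each database's identifier grammar in the
style of identifiers.org patterns, not authoritative identifiers.org entries.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IDPatternSpec",
    "Registry",
    "default_registry",
    "REFERENCE_CLASS_COUNTS",
    "reference_profile",
]

# A generator hint is a sequence of parts.  A part is either a literal string
# or a (alphabet, min_len, max_len) tuple meaning "min_len..max_len characters
# drawn uniformly from alphabet".
Part = str | tuple[str, int, int]

_DIGITS = "0123456789"
_NONZERO = "123456789"
_UPPER = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_LOWER = "abcdefghijklmnopqrstuvwxyz"
_HEXU = "0123456789ABCDEF"
_ALNUM_U = _UPPER + _DIGITS


class RegistryError(ValueError):
    """Invalid registry operation (duplicate name, bad template, ...)."""


class CapacityError(RegistryError):
    """More distinct identifiers requested than the template can produce."""


@dataclass(frozen=True)
class IDPatternSpec:
    """One database's identifier pattern.

    Parameters
    ----------
    name
        Class label, unique within a registry (e.g. ``"ChEMBL"``).
    template
        Anchored regular expression every identifier of the class matches.
    generator_hint
        Optional structured template used for sampling synthetic identifiers;
        every sampled string must match ``template``.
    description
        Free-text note on the database / identifier flavour.
    """

    name: str
    template: str
    generator_hint: tuple[Part, ...] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise RegistryError("pattern name must be non-empty")
        try:
            compiled = re.compile(self.template)
        except re.error as exc:
            raise RegistryError(f"template for {self.name!r} does not compile: {exc}") from exc
        object.__setattr__(self, "_compiled", compiled)
        if self.generator_hint is not None:
            object.__setattr__(self, "generator_hint", tuple(self.generator_hint))
            for part in self.generator_hint:
                if isinstance(part, str):
                    continue
                alphabet, lo, hi = part
                if not alphabet or lo < 0 or hi < lo:
                    raise RegistryError(f"bad generator segment {part!r} for {self.name!r}")

    @property
    def compiled(self) -> re.Pattern:
        return self._compiled  # type: ignore[attr-defined]

    def matches(self, query: str) -> bool:
        return self.compiled.fullmatch(query) is not None

    def capacity(self) -> int:
        """Number of distinct strings the generator hint can produce."""
        if self.generator_hint is None:
            raise RegistryError(f"{self.name!r} has no generator hint")
        total = 1
        for part in self.generator_hint:
            if isinstance(part, str):
                continue
            alphabet, lo, hi = part
            a = len(set(alphabet))
            total *= sum(a**length for length in range(lo, hi + 1))
        return total


def _hint_to_json(hint: tuple[Part, ...] | None) -> str:
    if hint is None:
        return ""
    return json.dumps([p if isinstance(p, str) else list(p) for p in hint])


def _hint_from_json(text: str) -> tuple[Part, ...] | None:
    if not text:
        return None
    parts = []
    for p in json.loads(text):
        parts.append(p if isinstance(p, str) else (p[0], int(p[1]), int(p[2])))
    return tuple(parts)


class Registry:
    """Insertion-ordered collection of :class:`IDPatternSpec`."""

    def __init__(self, specs: Iterable[IDPatternSpec] = ()) -> None:
        self._specs: dict[str, IDPatternSpec] = {}
        for spec in specs:
            self.register(spec)

    def __len__(self) -> int:
        return len(self._specs)

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __getitem__(self, name: str) -> IDPatternSpec:
        return self._specs[name]

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def register(self, spec: IDPatternSpec) -> "Registry":
        if spec.name in self._specs:
            raise RegistryError(f"pattern {spec.name!r} already registered")
        self._specs[spec.name] = spec
        return self

    def match(self, query: str) -> list[str]:
        """Class names whose template fully matches ``query``, in registry order."""
        if not query:
            return []
        return [name for name, spec in self._specs.items() if spec.matches(query)]

    # -- synthetic generation ------------------------------------------------

    def generate_ids(self, name: str, n: int, seed: int) -> list[str]:
        """Sample ``n`` distinct identifiers of class ``name``.

        Deterministic for a fixed seed.  Raises :class:`CapacityError` when
        ``n`` exceeds the number of distinct strings the hint can produce.
        """
        if name not in self._specs:
            raise RegistryError(f"unknown class {name!r}")
        spec = self._specs[name]
        if spec.generator_hint is None:
            raise RegistryError(f"{name!r} has no generator hint")
        if n < 0:
            raise ValueError("n must be >= 0")
        capacity = spec.capacity()
        if n > capacity:
            raise CapacityError(f"{name!r}: requested {n} ids but template capacity is {capacity}")
        rng = np.random.default_rng(seed)
        out: list[str] = []
        seen: set[str] = set()
        # Rejection sampling in batches; near-capacity requests degrade to
        # coupon collecting, which is fine at the small capacities where it
        # can occur.
        while len(out) < n:
            batch = max(256, int((n - len(out)) * 1.2))
            for s in _sample_batch(spec.generator_hint, batch, rng):
                if s not in seen:
                    seen.add(s)
                    out.append(s)
                    if len(out) == n:
                        break
        for s in out[: min(len(out), 8)]:
            if not spec.matches(s):  # pragma: no cover - template/hint invariant
                raise RegistryError(f"generated id {s!r} does not match template of {name!r}")
        return out

    def generate_dataset(self, profile: Mapping[str, int], seed: int) -> pd.DataFrame:
        """Build an ID table with ``profile[name]`` rows per class.

        Returns a two-column frame (``id``, ``class``); identifiers are unique
        within each class.  Per-class seeds are derived from ``seed`` so each
        class's sample is stable under profile changes.
        """
        validate_profile(profile, self)
        frames = []
        root = np.random.default_rng(seed)
        # independent child seed per class, order-stable
        child_seeds = {name: int(s) for name, s in
                       zip(profile, root.integers(0, 2**31 - 1, size=len(profile)))}
        for name, count in profile.items():
            ids = self.generate_ids(name, int(count), child_seeds[name])
            frames.append(pd.DataFrame({"id": ids, "class": name}))
        return pd.concat(frames, ignore_index=True)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        rows = [
            {
                "name": s.name,
                "template": s.template,
                "generator_hint": _hint_to_json(s.generator_hint),
                "description": s.description,
            }
            for s in self._specs.values()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "Registry":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        reg = cls()
        for _, row in df.iterrows():
            reg.register(
                IDPatternSpec(
                    name=row["name"],
                    template=row["template"],
                    generator_hint=_hint_from_json(row["generator_hint"]),
                    description=row["description"],
                )
            )
        return reg


def validate_profile(profile: Mapping[str, int], registry: Registry) -> None:
    if not profile:
        raise ValueError("profile is empty")
    for name, count in profile.items():
        if name not in registry:
            raise RegistryError(f"unknown class {name!r} in profile")
        if int(count) < 1:
            raise ValueError(f"profile count for {name!r} must be >= 1")


def _sample_batch(hint: Sequence[Part], m: int, rng: np.random.Generator) -> list[str]:
    """Sample ``m`` (not necessarily distinct) strings from a hint."""
    columns: list[list[str]] = []
    for part in hint:
        if isinstance(part, str):
            columns.append([part] * m)
            continue
        alphabet, lo, hi = part
        lengths = np.full(m, lo) if lo == hi else rng.integers(lo, hi + 1, size=m)
        total = int(lengths.sum())
        flat = rng.integers(0, len(alphabet), size=total)
        chars = np.asarray(list(alphabet))[flat]
        pieces: list[str] = []
        pos = 0
        for length in lengths:
            pieces.append("".join(chars[pos : pos + length]))
            pos += length
        columns.append(pieces)
    return ["".join(parts) for parts in zip(*columns)]


# ---------------------------------------------------------------------------
# Built-in registry: 39 database classes.  Generator hints are engineered so
# that the 39 synthetic class distributions are pairwise (near-)disjoint even
# where the regular expressions themselves overlap — real databases do share
# surface forms, and match() deliberately reports every matching class.
# ---------------------------------------------------------------------------

_BUILTIN: list[tuple[str, str, tuple[Part, ...], str]] = [
    ("The Consensus CDS", r"^CCDS\d{4,5}$", ("CCDS", (_DIGITS, 4, 5)), "CCDS ID"),
    ("Conserved Domain Database", r"^cd\d{5}$", ("cd", (_DIGITS, 5, 5)), "CDD ID"),
    ("ChEMBL", r"^CHEMBL\d+$", ("CHEMBL", (_DIGITS, 4, 6)), "ChEMBL ID"),
    ("EMBL", r"^[A-Z]{2}\d{6}$", ((_UPPER, 2, 2), (_DIGITS, 6, 6)), "European Nucleotide Archive ID"),
    ("Ensembl exon", r"^ENSE\d{11}$", ("ENSE", (_DIGITS, 11, 11)), "Exon stable ID"),
    ("Ensembl gene", r"^ENSG\d{11}$", ("ENSG", (_DIGITS, 11, 11)), "Gene stable ID"),
    ("Entrez Gene Database", r"^\d+$", ((_NONZERO, 1, 1), (_DIGITS, 2, 8)), "NCBI gene (formerly Entrezgene) ID"),
    ("HAMAP", r"^MF_\d{5}$", ("MF_", (_DIGITS, 5, 5)), "HAMAP ID"),
    ("HGNC", r"^HGNC:\d{1,5}$", ("HGNC:", (_DIGITS, 1, 5)), "HGNC ID"),
    ("HGNC Transcript", r"^[A-Z]{2,6}\d{0,2}-\d{3}$",
     ((_UPPER, 2, 6), (_DIGITS, 0, 2), "-", (_DIGITS, 3, 3)), "Transcript name ID"),
    ("PANTHER", r"^PTHR\d{5}$", ("PTHR", (_DIGITS, 5, 5)), "PANTHER ID"),
    ("Interpro", r"^IPR\d{6}$", ("IPR", (_DIGITS, 6, 6)), "Interpro ID"),
    ("Merops", r"^[A-Z]\d{2}\.\d{3}$", (("ACGIMNSTU", 1, 1), (_DIGITS, 2, 2), ".", (_DIGITS, 3, 3)),
     "MEROPS - the Peptidase Database ID"),
    ("miRBase", r"^MI\d{7}$", ("MI", (_DIGITS, 7, 7)), "miRBase ID"),
    ("Protein Data Bank", r"^[0-9][A-Z0-9]{3}$", ((_NONZERO, 1, 1), (_UPPER, 1, 1), (_ALNUM_U, 2, 2)),
     "PDB ID"),
    ("Pfam", r"^PF\d{5}$", ("PF", (_DIGITS, 5, 5)), "Pfam ID"),
    ("pfScan", r"^PS5\d{4}$", ("PS5", (_DIGITS, 4, 4)), "PROSITE profiles ID"),
    ("PIRSF", r"^PIRSF\d{6}$", ("PIRSF", (_DIGITS, 6, 6)), "PIRSF ID"),
    ("PRINTS", r"^PR\d{5}$", ("PR", (_DIGITS, 5, 5)), "Prints ID"),
    ("Protein", r"^[A-Z]{3}\d{5}$", ((_UPPER, 3, 3), (_DIGITS, 5, 5)), "INSDC protein ID"),
    ("Reactome", r"^R-HSA-\d{1,7}$", ("R-HSA-", (_DIGITS, 5, 7)), "Reactome gene ID"),
    ("Refseq mrna", r"^NM_\d{6,9}$", ("NM_", (_DIGITS, 6, 9)), "RefSeq mRNA ID"),
    ("Refseq ncrna", r"^NR_\d{6,9}$", ("NR_", (_DIGITS, 6, 9)), "RefSeq ncRNA ID"),
    ("Refseq peptide", r"^NP_\d{6,9}$", ("NP_", (_DIGITS, 6, 9)), "RefSeq peptide ID"),
    ("Rfam", r"^RF\d{5}$", ("RF", (_DIGITS, 5, 5)), "RFAM ID"),
    ("Rfam transcript", r"^[A-Z]{2,5}\d{0,2}\.\d{1,3}$",
     ((_UPPER, 2, 5), (_DIGITS, 0, 2), ".", (_DIGITS, 1, 3)), "RFAM transcript name ID"),
    ("RNAcentral", r"^URS[0-9A-F]{10}$", ("URS", (_HEXU, 10, 10)), "RNAcentral ID"),
    ("ScanProsite", r"^PS0\d{4}$", ("PS0", (_DIGITS, 4, 4)), "PROSITE patterns ID"),
    ("Structure-Function Linkage Database", r"^SFLD[FGS]\d{5}$",
     ("SFLD", ("FGS", 1, 1), (_DIGITS, 5, 5)), "SFLD ID"),
    ("SMART", r"^SM\d{5}$", ("SM", (_DIGITS, 5, 5)), "SMART ID"),
    ("SUPERFAMILY", r"^SSF\d{5}$", ("SSF", (_DIGITS, 5, 5)), "Superfamily ID"),
    ("TIGRFAMs", r"^TIGR\d{5}$", ("TIGR", (_DIGITS, 5, 5)), "TIGRFAM ID"),
    ("UCSC", r"^uc\d{3}[a-z]{3}\.\d$", ("uc", (_DIGITS, 3, 3), (_LOWER, 3, 3), ".", (_DIGITS, 1, 1)),
     "UCSC Stable ID"),
    ("UniProt Archive", r"^UPI[0-9A-F]{10}$", ("UPI", (_HEXU, 10, 10)), "UniParc ID"),
    ("Uniprot gene", r"^[A-Z]{2,6}\d{0,2}$", ((_UPPER, 2, 6), (_DIGITS, 0, 2)),
     "UniProtKB Gene Name symbol"),
    ("Uniprot isoform", r"^[OPQ][0-9][A-Z0-9]{3}[0-9]-\d{1,2}$",
     (("OPQ", 1, 1), (_DIGITS, 1, 1), (_ALNUM_U, 3, 3), (_DIGITS, 1, 1), "-", (_DIGITS, 1, 2)),
     "UniProtKB isoform ID"),
    ("Uniprot TrEMBL", r"^A0A\d{3}[A-Z][A-Z0-9]{3}$",
     ("A0A", (_DIGITS, 3, 3), (_UPPER, 1, 1), (_ALNUM_U, 3, 3)), "UniProtKB/TrEMBL ID"),
    ("Uniprot Swiss-prot", r"^[OPQ][0-9][A-Z0-9]{3}[0-9]$",
     (("OPQ", 1, 1), (_DIGITS, 1, 1), (_ALNUM_U, 3, 3), (_DIGITS, 1, 1)), "UniProtKB/Swiss-Prot ID"),
    ("WikiGene", r"^[A-Z][a-z]{2,6}\d{0,2}$", ((_UPPER, 1, 1), (_LOWER, 2, 6), (_DIGITS, 0, 2)),
     "WikiGene name"),
]


def default_registry() -> Registry:
    """The built-in 39-database registry (emulated templates)."""
    return Registry(IDPatternSpec(*row) for row in _BUILTIN)


#: Per-class corpus sizes of the Ensembl-derived reference corpus the model
#: family was originally trained on (the "imbalanced" profile); total
#: 2 751 478 rows with a ~14 702:1 majority/minority ratio.
REFERENCE_CLASS_COUNTS: dict[str, int] = {
    "The Consensus CDS": 32_717,
    "Conserved Domain Database": 7_204,
    "ChEMBL": 4_030,
    "EMBL": 199_350,
    "Ensembl exon": 852_763,
    "Ensembl gene": 68_016,
    "Entrez Gene Database": 22_927,
    "HAMAP": 358,
    "HGNC": 39_780,
    "HGNC Transcript": 232_496,
    "PANTHER": 23_775,
    "Interpro": 17_612,
    "Merops": 780,
    "miRBase": 1_846,
    "Protein Data Bank": 48_239,
    "Pfam": 6_595,
    "pfScan": 895,
    "PIRSF": 949,
    "PRINTS": 1_483,
    "Protein": 490_333,
    "Reactome": 2_495,
    "Refseq mrna": 62_046,
    "Refseq ncrna": 15_828,
    "Refseq peptide": 57_215,
    "Rfam": 58,
    "Rfam transcript": 1_461,
    "RNAcentral": 89_729,
    "ScanProsite": 881,
    "Structure-Function Linkage Database": 64,
    "SMART": 1_020,
    "SUPERFAMILY": 1_113,
    "TIGRFAMs": 594,
    "UCSC": 226_788,
    "UniProt Archive": 90_791,
    "Uniprot gene": 20_438,
    "Uniprot isoform": 24_825,
    "Uniprot TrEMBL": 61_771,
    "Uniprot Swiss-prot": 19_287,
    "WikiGene": 22_926,
}


def reference_profile() -> dict[str, int]:
    """Copy of the reference imbalanced per-class counts."""
    return dict(REFERENCE_CLASS_COUNTS)
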