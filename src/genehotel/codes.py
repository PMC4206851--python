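"""Genetic code tables, rule-generated anticodon tables, property scales.

The standard genetic code is built in.  The two codon->anticodon tables are
*generated from wobble rules* rather than transcribed codon by codon:

* **Standard tRNA code** — every box of synonymous NNC/NNU codons is read
  by the single 5'G anticodon (the reverse complement of the NNC codon);
  codons ending in A or G are read by their own reverse complement (5'U
  and 5'C respectively).  No anticodon starts with A, so the 16 ANN
  triplets are never used.
* **Human tRNA code** — eight boxes (Phe, Cys, Ser-AGY, Tyr, His, Asp,
  Asn, Gly) retain the 5'G anticodon for their NNC/NNU codons, while the
  other eight boxes (Ala, Pro, Thr, Val, Ser-UCN, Leu-CUN, Arg-CGN, Ile)
  use the 5'A anticodon whose A is modified to inosine; 3'A and 3'G codons
  are read by their reverse complements as in the standard set.  Eight ANN
  and eight GNN triplets end up unused.

Stop codons are never assigned an anticodon.  Each table's tRNA species
list is the set of distinct anticodons plus one dedicated initiator with
the same CAU anticodon as elongator Met.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from genehotel.algebra import ALL_TRIPLETS, named_subset, reverse_complement

STOP = "Stop"

AMINO_ACIDS = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

# Standard genetic code by family box (first two codon bases); each value
# lists the labels of the third-base C, U, A, G codons in that order.
_SGC_BOXES = {
    "UU": ("Phe", "Phe", "Leu", "Leu"),
    "UC": ("Ser", "Ser", "Ser", "Ser"),
    "UA": ("Tyr", "Tyr", STOP, STOP),
    "UG": ("Cys", "Cys", STOP, "Trp"),
    "CU": ("Leu", "Leu", "Leu", "Leu"),
    "CC": ("Pro", "Pro", "Pro", "Pro"),
    "CA": ("His", "His", "Gln", "Gln"),
    "CG": ("Arg", "Arg", "Arg", "Arg"),
    "AU": ("Ile", "Ile", "Ile", "Met"),
    "AC": ("Thr", "Thr", "Thr", "Thr"),
    "AA": ("Asn", "Asn", "Lys", "Lys"),
    "AG": ("Ser", "Ser", "Arg", "Arg"),
    "GU": ("Val", "Val", "Val", "Val"),
    "GC": ("Ala", "Ala", "Ala", "Ala"),
    "GA": ("Asp", "Asp", "Glu", "Glu"),
    "GG": ("Gly", "Gly", "Gly", "Gly"),
}

#: Boxes whose NNC/NNU codons keep the 5'G anticodon in the human set: the
#: seven dicodonic attributions of Phe, Cys, Ser(AGY), Tyr, His, Asp, Asn,
#: plus the tetracodonic Gly.
_HUMAN_G_RETAINED = frozenset({"UU", "UG", "AG", "UA", "CA", "GA", "AA", "GG"})

#: Polar requirement scale (chromatographic polarity of the free amino
#: acids, dimensionless).
POLAR_REQUIREMENT = {
    "Ala": 7.0, "Arg": 9.1, "Asn": 10.0, "Asp": 13.0, "Cys": 4.8,
    "Gln": 8.6, "Glu": 12.5, "Gly": 7.9, "His": 8.4, "Ile": 4.9,
    "Leu": 4.9, "Lys": 10.1, "Met": 5.3, "Phe": 5.0, "Pro": 6.6,
    "Ser": 7.5, "Thr": 6.6, "Trp": 5.2, "Tyr": 5.4, "Val": 5.6,
}

#: Kyte-Doolittle hydropathy index (dimensionless).
HYDROPATHY = {
    "Ala": 1.8, "Arg": -4.5, "Asn": -3.5, "Asp": -3.5, "Cys": 2.5,
    "Gln": -3.5, "Glu": -3.5, "Gly": -0.4, "His": -3.2, "Ile": 4.5,
    "Leu": 3.8, "Lys": -3.9, "Met": 1.9, "Phe": 2.8, "Pro": -1.6,
    "Ser": -0.8, "Thr": -0.7, "Trp": -0.9, "Tyr": -1.3, "Val": 4.2,
}


@dataclass(frozen=True)
class CodeTable:
    """A total codon -> label assignment (labels: amino acids or Stop)."""

    mapping: dict[str, str]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = set(ALL_TRIPLETS) - set(self.mapping)
        if missing:
            raise ValueError(
                f"code table {self.name!r} is not total; missing codons: "
                f"{', '.join(sorted(missing))}"
            )
        extra = set(self.mapping) - set(ALL_TRIPLETS)
        if extra:
            raise ValueError(
                f"code table {self.name!r} has invalid codons: "
                f"{', '.join(sorted(extra))}"
            )

    def __getitem__(self, codon: str) -> str:
        return self.mapping[codon]

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(self.mapping.values())

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, lab in self.mapping.items() if lab == STOP)

    @property
    def sense_codons(self) -> frozenset[str]:
        return frozenset(c for c, lab in self.mapping.items() if lab != STOP)

    def blocks(self) -> dict[str, frozenset[str]]:
        """Synonymous codon blocks: label -> codon set."""
        out: dict[str, set[str]] = {}
        for codon, lab in self.mapping.items():
            out.setdefault(lab, set()).add(codon)
        return {lab: frozenset(cs) for lab, cs in out.items()}

    def labels_on(self, subset) -> frozenset[str]:
        """Labels occurring on a triplet subset (e.g. the floor 'NNC')."""
        triplets = named_subset(subset) if isinstance(subset, str) else subset
        return frozenset(self.mapping[t] for t in triplets)


@dataclass(frozen=True)
class AnticodonTable:
    """Codon -> anticodon assignment with modification flags.

    ``mapping`` sends every sense codon to its (singleton) anticodon set;
    ``flags`` marks anticodons transcribed with 5'A and modified to inosine;
    ``species`` lists tRNA species as (anticodon, label) pairs, including
    one dedicated initiator (CAU, Met/initiator).
    """

    mapping: dict[str, frozenset[str]]
    flags: dict[str, str] = field(default_factory=dict)
    species: tuple[tuple[str, str], ...] = ()
    name: str = "custom"

    def __getitem__(self, codon: str) -> frozenset[str]:
        return self.mapping[codon]

    def used_anticodons(self) -> frozenset[str]:
        return frozenset().union(*self.mapping.values())

    def unused_triplets(self) -> frozenset[str]:
        """Triplets of the 64 that serve as no codon's anticodon."""
        return frozenset(ALL_TRIPLETS) - self.used_anticodons()

    def codons_of(self, anticodon: str) -> frozenset[str]:
        return frozenset(c for c, acs in self.mapping.items() if anticodon in acs)

    def anticodon_labels(self, code: CodeTable) -> dict[str, str]:
        """Label each used anticodon by the amino acid of the codons it
        serves (unambiguous in both built-in tables)."""
        out: dict[str, str] = {}
        for codon, acs in self.mapping.items():
            for ac in acs:
                lab = code[codon]
                if out.setdefault(ac, lab) != lab:
                    raise ValueError(
                        f"anticodon {ac} serves codons of different labels"
                    )
        return out

    @property
    def n_species(self) -> int:
        return len(self.species)


def sgc() -> CodeTable:
    """The standard genetic code: 61 sense codons, 3 stops, 21 labels."""
    mapping = {}
    for prefix, labels in _SGC_BOXES.items():
        for base, lab in zip("CUAG", labels):
            mapping[prefix + base] = lab
    return CodeTable(mapping=mapping, name="sgc")


def _species(mapping: dict[str, frozenset[str]], code: CodeTable):
    seen: dict[str, str] = {}
    for codon in sorted(mapping):
        for ac in mapping[codon]:
            seen.setdefault(ac, code[codon])
    elongators = tuple(sorted(seen.items()))
    return elongators + (("CAU", "Met(initiator)"),)


def standard_anticodons() -> AnticodonTable:
    """Rule-generated standard tRNA codon->anticodon table.

    45 distinct elongator anticodons (all of CNN, UNN, GNN except the three
    reverse complements of the stop codons) plus the initiator: 46 species.
    """
    code = sgc()
    mapping: dict[str, frozenset[str]] = {}
    for codon in sorted(code.sense_codons):
        if codon.endswith("U"):
            ac = reverse_complement(codon[:2] + "C")  # shared 5'G anticodon
        else:
            ac = reverse_complement(codon)
        mapping[codon] = frozenset({ac})
    table = AnticodonTable(
        mapping=mapping,
        flags={},
        species=_species(mapping, code),
        name="std-trna",
    )
    return table


def human_anticodons() -> AnticodonTable:
    """Rule-generated human tRNA codon->anticodon table.

    NNC/NNU codons share a single wobble anticodon per box: 5'G in the
    eight G-retained boxes, 5'A (modified to inosine) in the other eight.
    """
    code = sgc()
    mapping: dict[str, frozenset[str]] = {}
    flags: dict[str, str] = {}
    for codon in sorted(code.sense_codons):
        box = codon[:2]
        if codon[2] in "CU":
            if box in _HUMAN_G_RETAINED:
                ac = reverse_complement(box + "C")
            else:
                ac = reverse_complement(box + "U")
                flags[ac] = "inosine-5prime"
        else:
            ac = reverse_complement(codon)
        mapping[codon] = frozenset({ac})
    return AnticodonTable(
        mapping=mapping,
        flags=flags,
        species=_species(mapping, code),
        name="human-trna",
    )


# ---------------------------------------------------------------------------
# TSV I/O

def write_code(code: CodeTable, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["codon", "label"])
        for codon in sorted(code.mapping):
            w.writerow([codon, code.mapping[codon]])


def load_code(path) -> CodeTable:
    """Read a codon<TAB>label table (header row required, RNA uppercase)."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[0].lower() != "codon":
            raise ValueError(f"{path}: expected a header row starting with 'codon'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected codon<TAB>label")
            codon, label = row[0], row[1]
            if "T" in codon:
                raise ValueError(
                    f"{path}:{lineno}: {codon!r} contains T; codons must use "
                    "the RNA alphabet C, U, A, G"
                )
            if codon in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate codon {codon}")
            mapping[codon] = label
    return CodeTable(mapping=mapping, name=Path(path).stem)


def write_anticodons(table: AnticodonTable, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["codon", "anticodon", "flag"])
        for codon in sorted(table.mapping):
            for ac in sorted(table.mapping[codon]):
                w.writerow([codon, ac, table.flags.get(ac, "none")])


def load_anticodons(path) -> AnticodonTable:
    """Read a codon<TAB>anticodon<TAB>flag table."""
    mapping: dict[str, set[str]] = {}
    flags: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[0].lower() != "codon":
            raise ValueError(f"{path}: expected a header row starting with 'codon'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected codon<TAB>anticodon")
            codon, ac = row[0], row[1]
            for trip in (codon, ac):
                if "T" in trip:
                    raise ValueError(
                        f"{path}:{lineno}: {trip!r} contains T; use the RNA alphabet"
                    )
            mapping.setdefault(codon, set()).add(ac)
            if len(row) > 2 and row[2] not in ("", "none"):
                flags[ac] = row[2]
    frozen = {c: frozenset(a) for c, a in mapping.items()}
    return AnticodonTable(
        mapping=frozen,
        flags=flags,
        species=_species(frozen, sgc()),
        name=Path(path).stem,
    )


# ---------------------------------------------------------------------------
# Randomized codes (null models)

def permute_labels(code: CodeTable, mapping: dict[str, str]) -> CodeTable:
    """Relabel synonymous blocks by a label permutation (Stop fixed)."""
    new = {
        codon: mapping.get(lab, lab) for codon, lab in code.mapping.items()
    }
    return CodeTable(mapping=new, name=f"{code.name}-permuted")


def random_code(seed: int, scheme: str = "shuffle-labels") -> CodeTable:
    """A randomized variant of the standard code, reproducible per seed.

    ``shuffle-labels`` permutes the 20 amino-acid labels over the standard
    synonymous blocks (Stop fixed), preserving the block-size multiset.
    ``shuffle-codons`` deals the 64 codons at random into blocks with the
    standard block sizes.
    """
    rng = random.Random(seed)
    base = sgc()
    if scheme == "shuffle-labels":
        labels = sorted(set(AMINO_ACIDS))
        shuffled = labels[:]
        rng.shuffle(shuffled)
        return permute_labels(base, dict(zip(labels, shuffled)))
    if scheme == "shuffle-codons":
        codons = sorted(ALL_TRIPLETS)
        rng.shuffle(codons)
        mapping: dict[str, str] = {}
        i = 0
        for lab, block in sorted(base.blocks().items()):
            for _ in block:
                mapping[codons[i]] = lab
                i += 1
        return CodeTable(mapping=mapping, name="shuffle-codons")
    raise ValueError(f"unknown randomization scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Amino-acid property tables

@dataclass(frozen=True)
class PropertyTable:
    """A numeric amino-acid property with a binned color classing.

    Bins default to the quartile split of the 20 values; amino acids whose
    codons fall in more than one property class (Ser under polar
    requirement) carry a ``mixed`` sentinel class.
    """

    name: str
    values: dict[str, float]
    mixed: frozenset[str] = frozenset()
    n_bins: int = 4

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"property {self.name!r} missing values for {missing}")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]

    def bin_edges(self) -> np.ndarray:
        """Interior bin edges: equal-probability quantiles of the values."""
        vals = np.array(sorted(self.values.values()))
        qs = np.linspace(0, 1, self.n_bins + 1)[1:-1]
        return np.quantile(vals, qs)

    def class_of(self, aa: str) -> str:
        if aa in self.mixed:
            return "mixed"
        if aa not in self.values:
            raise KeyError(f"no {self.name} value for {aa!r}")
        idx = int(np.searchsorted(self.bin_edges(), self.values[aa], side="right"))
        return f"q{idx + 1}"

    def classes(self) -> dict[str, str]:
        return {aa: self.class_of(aa) for aa in self.values}


def properties(name: str) -> PropertyTable:
    """Packaged amino-acid property table: ``polar_requirement`` (with
    Ser flagged as mixed-class) or ``hydropathy``."""
    if name == "polar_requirement":
        return PropertyTable(
            name=name, values=dict(POLAR_REQUIREMENT), mixed=frozenset({"Ser"})
        )
    if name == "hydropathy":
        return PropertyTable(name=name, values=dict(HYDROPATHY))
    raise ValueError(f"unknown property {name!r}")
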