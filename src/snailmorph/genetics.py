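"""Clonal genetics: haplotype divergence and assignment, the dosage-agnostic
SNP genotype encoding, multilocus genotype collapsing, and missing-data-aware
genotype distances.

The SNP encoding follows the clonal (apomictic) logic: each variable locus
occupies two string positions, one per allelic state in alphabetical order,
so a homozygote is two identical characters and a heterozygote two different
ones.  Allele dosage is deliberately not modelled (presence/absence assays
cannot resolve it in polyploids).  Missing data is the pair "??".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = "?"
_SKIP = set("N-" + MISSING)


class AlignmentError(ValueError):
    """Raised when sequences or encoded genotypes have unequal lengths."""


@dataclass
class HaplotypeReference:
    name: str
    sequence: str

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN-")
        if bad:
            raise ValueError(f"{self.name}: invalid symbols {bad}")

    def __len__(self):
        return len(self.sequence)


def read_fasta(path) -> list[HaplotypeReference]:
    return [HaplotypeReference(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(references, path) -> None:
    records = [SeqRecord(Seq(r.sequence), id=r.name, description="") for r in references]
    SeqIO.write(records, str(path), "fasta")


def pairwise_divergence(seq_a: str, seq_b: str) -> tuple[int, float]:
    """Count and percentage of differing sites between two aligned sequences.

    Sites where either sequence has N, '-' or '?' are excluded from both the
    numerator and the denominator.  The percentage is rounded half-up to two
    decimals (the convention used when divergences are reported in print).
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise AlignmentError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    compared = diffs = 0
    for x, y in zip(a, b):
        if x in _SKIP or y in _SKIP:
            continue
        compared += 1
        if x != y:
            diffs += 1
    if compared == 0:
        return 0, 0.0
    import decimal

    pct = decimal.Decimal(100 * diffs) / decimal.Decimal(compared)
    pct = float(pct.quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))
    return diffs, pct


@dataclass
class HaplotypeAssignment:
    name: str
    distance: int
    ambiguous: bool = False
    candidates: list[str] = field(default_factory=list)
    novel: bool = False
    suggested_name: str | None = None


def assign_haplotype(query: str, references: list[HaplotypeReference]) -> HaplotypeAssignment:
    """Assign a query sequence to the nearest reference haplotype.

    Exact matches get distance 0; a query one or more substitutions away is
    flagged as a novel variant with a suggested derived name (reference name
    + "2"); ties are flagged ambiguous with all minimal candidates listed.
    """
    if not references:
        raise ValueError("empty reference set")
    dists = []
    for ref in references:
        if len(ref) != len(query):
            raise AlignmentError(
                f"query length {len(query)} != reference {ref.name} length {len(ref)}"
            )
        d, _ = pairwise_divergence(query, ref.sequence)
        dists.append((d, ref.name))
    dmin = min(d for d, _ in dists)
    winners = [name for d, name in dists if d == dmin]
    if len(winners) > 1:
        return HaplotypeAssignment(winners[0], dmin, ambiguous=True, candidates=winners)
    name = winners[0]
    if dmin == 0:
        return HaplotypeAssignment(name, 0)
    return HaplotypeAssignment(name, dmin, novel=True, suggested_name=f"{name}2")


# ---------------------------------------------------------------------------
# Multilocus genotypes
# ---------------------------------------------------------------------------

class PloidyEncodingError(ValueError):
    """More than two distinct alleles at one locus (assays detect presence only)."""


def encode_call(call) -> str:
    """Encode one locus call as a two-character string.

    Accepts "A" (homozygote), "A/G", "AG", {"A", "G"} (heterozygote) or
    "?"/""/None (missing).  Alleles are sorted alphabetically.
    """
    if call is None:
        return MISSING * 2
    if isinstance(call, str):
        alleles = [a for a in call.replace("/", "") if a.strip()]
    else:
        alleles = list(call)
    if not alleles or alleles == [MISSING] or set(alleles) == {MISSING}:
        return MISSING * 2
    alleles = [a.upper() for a in alleles]
    distinct = sorted(set(alleles))
    if any(a not in "ACGT" for a in distinct):
        raise ValueError(f"invalid allele symbols in {call!r}")
    if len(distinct) == 1:
        return distinct[0] * 2
    if len(distinct) == 2:
        return distinct[0] + distinct[1]
    raise PloidyEncodingError(f"more than two alleles at a locus: {call!r}")


def encode_genotype(calls) -> str:
    """Concatenate per-locus two-character encodings in the given locus order."""
    return "".join(encode_call(c) for c in calls)


def decode_genotype(encoded: str) -> list[str]:
    """Inverse of :func:`encode_genotype`: list of per-locus call strings."""
    if len(encoded) % 2:
        raise ValueError("encoded genotype must have even length")
    calls = []
    for i in range(0, len(encoded), 2):
        a, b = encoded[i], encoded[i + 1]
        if MISSING in (a, b):
            calls.append(MISSING)
        elif a == b:
            calls.append(a)
        else:
            calls.append(f"{a}/{b}")
    return calls


@dataclass
class MultilocusGenotype:
    """A named clonal multilocus genotype."""

    genotype_id: str
    encoded: str
    count: int = 1
    members: list[str] = field(default_factory=list)
    haplotype: str | None = None
    loci: list[str] = field(default_factory=list)

    @property
    def n_loci(self) -> int:
        return len(self.encoded) // 2

    def n_heterozygous(self) -> int:
        return sum(
            1
            for i in range(0, len(self.encoded), 2)
            if MISSING not in self.encoded[i:i + 2]
            and self.encoded[i] != self.encoded[i + 1]
        )

    def n_missing_loci(self) -> int:
        return sum(
            1 for i in range(0, len(self.encoded), 2)
            if MISSING in self.encoded[i:i + 2]
        )


def mlg_distance(g_a, g_b) -> int:
    """Positions with unequal non-missing symbols, under pairwise deletion.

    Positions where either genotype carries the missing symbol are skipped.
    Symmetric with zero self-distance; the triangle inequality is not
    guaranteed under pairwise deletion, so this is a pseudo-metric.
    """
    a = g_a.encoded if isinstance(g_a, MultilocusGenotype) else g_a
    b = g_b.encoded if isinstance(g_b, MultilocusGenotype) else g_b
    if len(a) != len(b):
        raise AlignmentError(f"encoded lengths differ: {len(a)} vs {len(b)}")
    return sum(
        1 for x, y in zip(a, b)
        if x != MISSING and y != MISSING and x != y
    )


def collapse_mlg(encoded_individuals, specimen_ids=None,
                 haplotypes=None, loci=None) -> list[MultilocusGenotype]:
    """Collapse individuals sharing identical encoded strings into genotypes.

    The missing symbol is treated as a distinct literal, so two individuals
    differing only in missingness form separate genotypes.  Genotypes are
    numbered by descending abundance, ties broken by first appearance.
    """
    encoded = list(encoded_individuals)
    if not encoded:
        return []
    length = len(encoded[0])
    for e in encoded:
        if len(e) != length:
            raise AlignmentError("encoded genotype lengths differ")
    if specimen_ids is None:
        specimen_ids = [str(i) for i in range(len(encoded))]
    groups: dict[str, dict] = {}
    for idx, (e, sid) in enumerate(zip(encoded, specimen_ids)):
        if e not in groups:
            groups[e] = {"members": [], "first": idx, "haplotype": None}
        groups[e]["members"].append(sid)
        if haplotypes is not None and groups[e]["haplotype"] is None:
            groups[e]["haplotype"] = list(haplotypes)[idx]
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]["members"]), kv[1]["first"]))
    return [
        MultilocusGenotype(
            genotype_id=str(rank + 1), encoded=e, count=len(info["members"]),
            members=info["members"], haplotype=info["haplotype"],
            loci=list(loci) if loci else [],
        )
        for rank, (e, info) in enumerate(ordered)
    ]


def locus_variability(genotypes: list[MultilocusGenotype]) -> tuple[list[int], list[int]]:
    """Indices of fixed and variable loci across a genotype set (missing ignored)."""
    if not genotypes:
        return [], []
    n_loci = genotypes[0].n_loci
    fixed, variable = [], []
    for locus in range(n_loci):
        states = {
            g.encoded[2 * locus: 2 * locus + 2]
            for g in genotypes
            if MISSING not in g.encoded[2 * locus: 2 * locus + 2]
        }
        (variable if len(states) > 1 else fixed).append(locus)
    return fixed, variable


# ---------------------------------------------------------------------------
# Genotype table I/O and the published reference genotype set
# ---------------------------------------------------------------------------

def read_genotype_csv(path) -> pd.DataFrame:
    """Read a genotype call table: specimen_id, site_id, then one column per
    locus with values like "A", "A/G" or "?"."""
    df = pd.read_csv(path, dtype=str).fillna(MISSING)
    required = {"specimen_id", "site_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"genotype CSV must contain columns {sorted(required)}")
    return df


def encode_genotype_table(df: pd.DataFrame) -> pd.Series:
    """Encode each row of a genotype call table; index = specimen_id."""
    loci = [c for c in df.columns if c not in ("specimen_id", "site_id", "haplotype")]
    encoded = df[loci].apply(lambda row: encode_genotype(row.tolist()), axis=1)
    encoded.index = df["specimen_id"]
    return encoded


def reference_genotypes() -> list[MultilocusGenotype]:
    """The ten published clonal reference genotypes over 16 variable SNP loci.

    The bundled table preserves the published alignment verbatim: each locus
    is two positions in the printed order (dot-notation already expanded
    against genotype 1), with "??" for missing loci.  Eight genotypes carry
    the freshwater t/22 mitochondrial lineage and two the z2/37 lineage.
    """
    with resources.files("snailmorph.data").joinpath("table2_genotypes.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str)
    loci = [c for c in df.columns if c not in ("genotype", "haplotype")]
    return [
        MultilocusGenotype(
            genotype_id=row["genotype"],
            encoded="".join(row[loc] for loc in loci),
            haplotype=row["haplotype"],
            loci=loci,
        )
        for _, row in df.iterrows()
    ]
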