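"""Per-locus alignment handling: reading, validation, site classification.

A locus is one gap-aware multiple alignment of phased ingroup haplotypes from
one or two species plus exactly one outgroup sequence, with an exon annotation
on alignment coordinates (0-based, half-open).  Minus-strand annotations are
reverse-complemented at load time so all downstream code sees the coding
strand.

Columns containing a gap ('-') or an ambiguous base ('N' or anything outside
ACGT) in any row — ingroup or outgroup — are excluded from every statistic;
remaining columns are classed coding / noncoding from the annotation, and
coding columns carry fractional synonymous / nonsynonymous site weights
(Nei–Gojobori counting on the first ingroup haplotype).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BASES = (b"A", b"C", b"G", b"T")
_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"

# column classes
EXCLUDED_INDEL = 0
EXCLUDED_AMBIGUOUS = 1
NONCODING = 2
CODING = 3

# observed-variant effect codes
NO_VARIANT = -1
EFFECT_NONCODING = 0
EFFECT_SYNONYMOUS = 1
EFFECT_NONSYNONYMOUS = 2

EFFECT_NAMES = {EFFECT_NONCODING: "noncoding",
                EFFECT_SYNONYMOUS: "synonymous",
                EFFECT_NONSYNONYMOUS: "nonsynonymous"}


@dataclass
class LocusAlignment:
    """Validated alignment for one locus.

    ``seqs`` is the (n_ingroup x L) byte matrix of ingroup haplotypes;
    ``outgroup_seq`` the matching outgroup row.  ``exons`` are 0-based
    half-open intervals on alignment coordinates, already on the coding
    strand (``strand`` is retained for provenance only).
    """

    locus_id: str
    ids: list[str]
    species: list[str]
    populations: list[str]
    seqs: np.ndarray
    outgroup_id: str
    outgroup_seq: np.ndarray
    exons: list[tuple[int, int]]
    strand: str = "+"
    frame: int = 0

    def __post_init__(self):
        n = len(self.ids)
        if n == 0:
            raise ValueError(f"locus {self.locus_id}: zero ingroup rows")
        if not (len(self.species) == len(self.populations) == n):
            raise ValueError(f"locus {self.locus_id}: metadata length mismatch")
        self.seqs = np.asarray(self.seqs, dtype="S1")
        self.outgroup_seq = np.asarray(self.outgroup_seq, dtype="S1")
        if self.seqs.ndim != 2:
            raise ValueError("seqs must be a 2-D matrix")
        if self.outgroup_seq.shape != (self.L,):
            raise ValueError(
                f"locus {self.locus_id}: unequal alignment length "
                f"(outgroup {self.outgroup_seq.shape[0]} vs ingroup {self.L})")
        if len(set(self.species)) > 2:
            raise ValueError(
                f"locus {self.locus_id}: more than two ingroup species: "
                f"{sorted(set(self.species))}")
        last = 0
        for s, e in sorted(self.exons):
            if s < last:
                raise ValueError("overlapping exon intervals")
            if not (0 <= s < e <= self.L):
                raise ValueError("exon interval outside alignment")
            last = e
        self.exons = sorted(self.exons)
        cds_len = sum(e - s for s, e in self.exons)
        if cds_len and (cds_len - self.frame) % 3 != 0:
            raise ValueError(
                f"locus {self.locus_id}: exon length {cds_len} minus frame "
                f"{self.frame} not divisible by 3")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def L(self) -> int:
        return self.seqs.shape[1]

    def species_rows(self, species: str) -> np.ndarray:
        rows = np.asarray([s == species for s in self.species])
        if not rows.any():
            raise ValueError(f"locus {self.locus_id}: no rows for species {species!r}")
        return rows

    @property
    def species_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.species:
            if s not in seen:
                seen.append(s)
        return seen


@dataclass
class SiteClassification:
    """Per-column classification and fractional site weights for one locus."""

    col_class: np.ndarray      # EXCLUDED_* / NONCODING / CODING per column
    syn_weight: np.ndarray     # fractional synonymous sites per column
    nonsyn_weight: np.ndarray  # fractional nonsynonymous sites per column
    effect: np.ndarray         # observed-variant effect per column (codes above)
    n_skipped_codons: int = 0
    triallelic_columns: list[int] = field(default_factory=list)

    @property
    def analyzable(self) -> np.ndarray:
        return self.col_class >= NONCODING

    def filter_mask(self, name: str) -> np.ndarray:
        """Columns carrying an observed variant of the class (numerator mask);
        monomorphic columns never contribute to any numerator."""
        try:
            return CLASS_FILTERS[name](self)
        except KeyError:
            raise ValueError(f"unknown class filter {name!r}") from None

    def effective_sites(self, name: str) -> float:
        """Fractional analyzable site count for a class filter (denominator)."""
        noncoding = float(np.sum(self.col_class == NONCODING))
        syn = float(self.syn_weight.sum())
        nonsyn = float(self.nonsyn_weight.sum())
        if name == "all":
            return float(self.analyzable.sum())
        if name == "silent":
            return noncoding + syn
        if name == "synonymous":
            return syn
        if name == "nonsynonymous":
            return nonsyn
        if name == "noncoding":
            return noncoding
        raise ValueError(f"unknown class filter {name!r}")


CLASS_FILTERS = {
    "all": lambda c: c.analyzable & (c.effect >= NO_VARIANT),
    "silent": lambda c: c.analyzable & ((c.effect == EFFECT_NONCODING)
                                        | (c.effect == EFFECT_SYNONYMOUS)
                                        | (c.effect == NO_VARIANT)),
    "synonymous": lambda c: c.analyzable & ((c.effect == EFFECT_SYNONYMOUS)
                                            | (c.effect == NO_VARIANT)),
    "nonsynonymous": lambda c: c.analyzable & ((c.effect == EFFECT_NONSYNONYMOUS)
                                               | (c.effect == NO_VARIANT)),
    "noncoding": lambda c: c.analyzable & ((c.effect == EFFECT_NONCODING)
                                           | (c.effect == NO_VARIANT)),
}


@dataclass
class VariantRecord:
    """One polarized segregating or fixed-difference column."""

    column: int
    effect: str                      # synonymous | nonsynonymous | noncoding
    alleles: tuple[str, ...]
    outgroup_allele: str
    status: str                      # polymorphic_sp1/_sp2/_both | fixed_difference_vs_outgroup
    species_state: dict              # species -> polymorphic | fixed_difference | monomorphic
    counts: dict                     # species -> {allele: count}
    triallelic: bool = False


@dataclass
class PolarizedVariants:
    locus_id: str
    species_order: list[str]
    records: list[VariantRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


# ---------------------------------------------------------------------------
# reading / writing


def read_locus(fasta_path, metadata_table, annotation,
               locus_id: str | None = None,
               expected_species: tuple[str, ...] | None = None) -> LocusAlignment:
    """Read and validate one locus from FASTA + metadata + exon annotation.

    ``metadata_table`` is a TSV path or DataFrame with columns haplotype_id,
    species, population, is_outgroup; ``annotation`` a list of (start, end)
    intervals, a dict {exons, strand, frame}, or a GFF3/TSV path.
    """
    fasta_path = Path(fasta_path)
    if locus_id is None:
        locus_id = fasta_path.stem
    meta = (metadata_table if isinstance(metadata_table, pd.DataFrame)
            else pd.read_csv(metadata_table, sep="\t", dtype=str))
    meta = meta.set_index("haplotype_id", drop=False)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"{fasta_path}: empty or unparseable FASTA")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"locus {locus_id}: unequal alignment length {sorted(lengths)}")

    exons, strand, frame = _parse_annotation(annotation)

    ids, species, pops, seq_rows = [], [], [], []
    outgroup = None
    for r in records:
        if r.id not in meta.index:
            raise ValueError(f"locus {locus_id}: id {r.id!r} missing from metadata")
        row = meta.loc[r.id]
        is_out = str(row["is_outgroup"]).strip().lower() in ("1", "true", "yes")
        arr = np.frombuffer(str(r.seq).upper().encode(), dtype="S1")
        if is_out:
            if outgroup is not None:
                raise ValueError(f"locus {locus_id}: more than one outgroup row")
            outgroup = (r.id, arr)
        else:
            if expected_species is not None and row["species"] not in expected_species:
                raise ValueError(
                    f"locus {locus_id}: id {r.id!r} has species "
                    f"{row['species']!r}, expected one of {expected_species}")
            ids.append(r.id)
            species.append(str(row["species"]))
            pops.append(str(row["population"]))
            seq_rows.append(arr)
    if outgroup is None:
        raise ValueError(f"locus {locus_id}: no row flagged is_outgroup")
    if not ids:
        raise ValueError(f"locus {locus_id}: zero ingroup rows")

    seqs = np.vstack(seq_rows)
    out_id, out_seq = outgroup
    if strand == "-":
        L = seqs.shape[1]
        seqs = _revcomp(seqs)
        out_seq = _revcomp(out_seq[None, :])[0]
        exons = sorted((L - e, L - s) for s, e in exons)
        logger.info("locus %s: minus-strand annotation reverse-complemented", locus_id)
        strand = "+"
    return LocusAlignment(locus_id=locus_id, ids=ids, species=species,
                          populations=pops, seqs=seqs, outgroup_id=out_id,
                          outgroup_seq=out_seq, exons=exons, strand=strand,
                          frame=frame)


_COMP = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A", b"-": b"-", b"N": b"N"}


def _revcomp(seqs: np.ndarray) -> np.ndarray:
    out = np.full_like(seqs, b"N")
    for a, b in _COMP.items():
        out[seqs == a] = b
    return out[:, ::-1]


def _parse_annotation(annotation):
    if isinstance(annotation, dict):
        return (sorted(tuple(x) for x in annotation.get("exons", [])),
                annotation.get("strand", "+"), int(annotation.get("frame", 0)))
    if isinstance(annotation, (list, tuple)):
        return sorted(tuple(x) for x in annotation), "+", 0
    path = Path(annotation)
    if path.suffix.lower() in (".gff", ".gff3"):
        exons, strand, frame = [], "+", 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if f[2].lower() != "exon":
                    continue
                exons.append((int(f[3]) - 1, int(f[4])))  # GFF is 1-based inclusive
                strand = f[6]
                if not exons[1:] and f[7] in "012":
                    frame = int(f[7])
        return sorted(exons), strand, frame
    tab = pd.read_csv(path, sep="\t")
    strand = str(tab["strand"].iloc[0]) if "strand" in tab else "+"
    frame = int(tab["frame"].iloc[0]) if "frame" in tab else 0
    return sorted(zip(tab["start"].astype(int), tab["end"].astype(int))), strand, frame


def write_locus(aln: LocusAlignment, fasta_path, metadata_path=None,
                annotation_path=None) -> None:
    """Write a locus back to FASTA (+ optional metadata TSV and exon TSV)."""
    recs = []
    for i, hid in enumerate(aln.ids):
        recs.append(SeqRecord(Seq(aln.seqs[i].tobytes().decode()), id=hid, description=""))
    recs.append(SeqRecord(Seq(aln.outgroup_seq.tobytes().decode()),
                          id=aln.outgroup_id, description=""))
    SeqIO.write(recs, str(fasta_path), "fasta")
    if metadata_path is not None:
        meta = pd.DataFrame({
            "haplotype_id": aln.ids + [aln.outgroup_id],
            "species": aln.species + ["outgroup"],
            "population": aln.populations + ["outgroup"],
            "is_outgroup": [0] * aln.n + [1],
        })
        meta.to_csv(metadata_path, sep="\t", index=False)
    if annotation_path is not None:
        ann = pd.DataFrame(aln.exons, columns=["start", "end"])
        ann["strand"] = aln.strand
        ann["frame"] = aln.frame
        ann.to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# site classification


def _coding_map(aln: LocusAlignment):
    """Alignment columns of the CDS in reading order, frame offset applied."""
    cols = np.concatenate([np.arange(s, e) for s, e in aln.exons]) if aln.exons \
        else np.array([], dtype=int)
    return cols[aln.frame:]


def exclude_indels(aln: LocusAlignment) -> SiteClassification:
    """Mark excluded columns and compute site classes and Nei–Gojobori weights.

    A column is excluded if any row (ingroup or outgroup) carries '-'
    (excluded_indel) or any base outside ACGT (excluded_ambiguous).  Codons
    are 'intact' when all three columns are analyzable; only intact codons
    contribute synonymous / nonsynonymous site weights, computed from the
    first ingroup haplotype by enumerating the three alternative bases at
    each codon position under the standard genetic code.
    """
    all_rows = np.vstack([aln.seqs, aln.outgroup_seq])
    has_gap = (all_rows == b"-").any(axis=0)
    is_base = np.zeros_like(all_rows, dtype=bool)
    for b in BASES:
        is_base |= all_rows == b
    has_ambig = ~is_base.all(axis=0) & ~has_gap

    col_class = np.full(aln.L, NONCODING, dtype=np.int8)
    coding_cols = _coding_map(aln)
    col_class[coding_cols] = CODING
    col_class[has_ambig] = EXCLUDED_AMBIGUOUS
    col_class[has_gap] = EXCLUDED_INDEL

    syn_w = np.zeros(aln.L)
    nonsyn_w = np.zeros(aln.L)
    ref = aln.seqs[0]
    analyzable = col_class >= NONCODING
    n_codons = len(coding_cols) // 3
    n_skipped = 0
    for ci in range(n_codons):
        cods = coding_cols[3 * ci: 3 * ci + 3]
        if not analyzable[cods].all():
            continue
        codon = b"".join(ref[cods]).decode()
        if codon not in _CODON_TO_AA:
            n_skipped += 1
            continue
        if _CODON_TO_AA[codon] == "*":
            warnings.warn(f"locus {aln.locus_id}: premature stop codon "
                          f"{codon} at codon {ci}; skipped")
            n_skipped += 1
            continue
        for pos in range(3):
            syn = 0
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1:]
                if _CODON_TO_AA.get(mut) == _CODON_TO_AA[codon]:
                    syn += 1
            syn_w[cods[pos]] = syn / 3.0
            nonsyn_w[cods[pos]] = 1.0 - syn / 3.0

    classes = SiteClassification(col_class=col_class, syn_weight=syn_w,
                                 nonsyn_weight=nonsyn_w,
                                 effect=np.full(aln.L, NO_VARIANT, dtype=np.int8),
                                 n_skipped_codons=n_skipped)
    _assign_effects(aln, classes, coding_cols)
    return classes


def _codon_context(coding_cols: np.ndarray):
    """column -> (codon index, position in codon) for coding columns."""
    ctx = {}
    for i, col in enumerate(coding_cols):
        ctx[int(col)] = (i // 3, i % 3)
    return ctx


def _variant_effect(aln: LocusAlignment, classes: SiteClassification,
                    coding_cols: np.ndarray, ctx: dict,
                    col: int, alt: bytes) -> int:
    """Effect of replacing the reference base by ``alt`` at one column."""
    if classes.col_class[col] != CODING:
        return EFFECT_NONCODING
    ci, pos = ctx[col]
    cods = coding_cols[3 * ci: 3 * ci + 3]
    if not classes.analyzable[cods].all():
        return EFFECT_NONCODING  # non-intact codon: conservative, logged upstream
    ref = aln.seqs[0]
    codon = b"".join(ref[cods]).decode()
    if codon not in _CODON_TO_AA or _CODON_TO_AA[codon] == "*":
        return EFFECT_NONCODING
    mut = codon[:pos] + alt.decode() + codon[pos + 1:]
    if mut not in _CODON_TO_AA:
        return EFFECT_NONCODING
    same = _CODON_TO_AA[mut] == _CODON_TO_AA[codon]
    return EFFECT_SYNONYMOUS if same else EFFECT_NONSYNONYMOUS


def _assign_effects(aln: LocusAlignment, classes: SiteClassification,
                    coding_cols: np.ndarray) -> None:
    """Classify the observed change at every analyzable variable column.

    Variation is assessed over ingroup plus outgroup; the effect is that of
    the most frequent non-reference allele (tri-allelic columns are retained
    as single segregating sites and logged).
    """
    ctx = _codon_context(coding_cols)
    all_rows = np.vstack([aln.seqs, aln.outgroup_seq])
    analyzable = classes.analyzable
    variable = np.zeros(aln.L, dtype=bool)
    variable[analyzable] = (all_rows[:, analyzable] != all_rows[0, analyzable]).any(axis=0)
    ref = aln.seqs[0]
    for col in np.nonzero(variable)[0]:
        col = int(col)
        column = all_rows[:, col]
        alleles, counts = np.unique(column, return_counts=True)
        if len(alleles) > 2:
            classes.triallelic_columns.append(col)
            logger.info("locus %s: tri-allelic column %d retained as one "
                        "segregating site", aln.locus_id, col)
        non_ref = [(int(c), a) for a, c in zip(alleles, counts) if a != ref[col]]
        non_ref.sort(key=lambda t: (-t[0], t[1]))
        alt = non_ref[0][1]
        classes.effect[col] = _variant_effect(aln, classes, coding_cols, ctx, col, alt)


def count_site_classes(aln: LocusAlignment,
                       classes: SiteClassification) -> tuple[float, float, float]:
    """(nonsynonymous, synonymous, noncoding) analyzable site counts."""
    return (classes.effective_sites("nonsynonymous"),
            classes.effective_sites("synonymous"),
            classes.effective_sites("noncoding"))


# ---------------------------------------------------------------------------
# polarization


def polarize(aln: LocusAlignment, classes: SiteClassification) -> PolarizedVariants:
    """Polarize every analyzable variable column against the outgroup.

    Per species, a column is polymorphic when it carries >1 ingroup allele,
    and a fixed difference when the species is monomorphic for an allele that
    differs from the outgroup.  The overall status records which species are
    polymorphic; columns polymorphic in no species are fixed differences.
    """
    species_order = aln.species_labels
    sp_rows = {sp: aln.species_rows(sp) for sp in species_order}
    records: list[VariantRecord] = []
    analyzable = classes.analyzable
    all_rows = np.vstack([aln.seqs, aln.outgroup_seq])
    variable = np.zeros(aln.L, dtype=bool)
    variable[analyzable] = (all_rows[:, analyzable] != all_rows[0, analyzable]).any(axis=0)
    for col in np.nonzero(variable)[0]:
        col = int(col)
        out_allele = aln.outgroup_seq[col].decode()
        counts = {}
        state = {}
        for sp in species_order:
            column = aln.seqs[sp_rows[sp], col]
            a, c = np.unique(column, return_counts=True)
            counts[sp] = {al.decode(): int(ct) for al, ct in zip(a, c)}
            if len(a) > 1:
                state[sp] = "polymorphic"
            elif a[0].decode() != out_allele:
                state[sp] = "fixed_difference"
            else:
                state[sp] = "monomorphic"
        poly = [sp for sp in species_order if state[sp] == "polymorphic"]
        if len(poly) == len(species_order) and len(species_order) > 1:
            status = "polymorphic_both"
        elif poly:
            status = f"polymorphic_sp{species_order.index(poly[0]) + 1}"
        elif any(v == "fixed_difference" for v in state.values()):
            status = "fixed_difference_vs_outgroup"
        else:
            continue  # e.g. only the outgroup differs ambiguously — not reachable
        alleles = tuple(sorted({al for d in counts.values() for al in d} | {out_allele}))
        records.append(VariantRecord(
            column=col, effect=EFFECT_NAMES[int(classes.effect[col])],
            alleles=alleles, outgroup_allele=out_allele, status=status,
            species_state=state, counts=counts,
            triallelic=col in classes.triallelic_columns))
    return PolarizedVariants(locus_id=aln.locus_id,
                             species_order=species_order, records=records)
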