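"""Allele-fraction genotype calling and the IUPAC-encoded SNP matrix.

The calling rule reproduces a depth/allele-fraction filter stack used in
diploid yeast resequencing: a site is missing (N) when its depth is
below 15 or above four times the isolate's median depth; the top allele
is called homozygous when it carries at least 80% of the reads; the top
two alleles are called heterozygous (encoded as a IUPAC ambiguity code)
when the second allele carries at least 20% of the reads; anything else
— including three alleles each at >= 20% — is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

BASE_ORDER = "ACGT"
COUNT_COLS = ["countA", "countC", "countG", "countT"]

#: IUPAC ambiguity code for each unordered pair of bases.
IUPAC_CODE = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
#: Inverse map: het code -> the two bases it encodes (alphabetical).
IUPAC_ALLELES = {code: tuple(sorted(pair)) for pair, code in IUPAC_CODE.items()}
HET_CODES = frozenset(IUPAC_ALLELES)


def expand_call(call: str) -> tuple[str, str]:
    """Diploid allele copies encoded by a call; N has no copies."""
    if call in IUPAC_ALLELES:
        return IUPAC_ALLELES[call]
    if call in BASE_ORDER:
        return (call, call)
    raise ValueError(f"cannot expand call {call!r}")


@dataclass(frozen=True)
class CallParams:
    min_depth: int = 15
    max_depth_factor: float = 4.0
    hom_fraction: float = 0.80
    het_fraction: float = 0.20


def call_genotype(counts: Mapping[str, int] | Iterable[int], depth: int,
                  sample_median_depth: float,
                  params: CallParams = CallParams()) -> str:
    """Call one site; see module docstring for the rule."""
    if sample_median_depth <= 0:
        raise ValueError("sample median depth must be positive")
    if isinstance(counts, Mapping):
        c = np.array([counts.get(b, 0) for b in BASE_ORDER], dtype=np.int64)
    else:
        c = np.asarray(list(counts), dtype=np.int64)
    if c.sum() > depth:
        raise ValueError("allele counts exceed depth")
    calls = call_genotypes_vector(
        c[None, :], np.array([depth]), sample_median_depth, params)
    return calls[0]


def call_genotypes_vector(counts: np.ndarray, depth: np.ndarray,
                          sample_median_depth: float,
                          params: CallParams = CallParams()) -> np.ndarray:
    """Vectorised genotype calling over (n_sites, 4) count rows."""
    n = counts.shape[0]
    depth = depth.astype(np.int64)
    if np.any(counts.sum(axis=1) > depth):
        raise ValueError("allele counts exceed depth")
    order = np.argsort(counts, axis=1, kind="stable")  # ascending; ties -> lower index first
    top1 = order[:, -1]
    top2 = order[:, -2]
    c1 = counts[np.arange(n), top1].astype(float)
    c2 = counts[np.arange(n), top2].astype(float)
    c3 = counts[np.arange(n), order[:, -3]].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(depth > 0, c1 / depth, 0.0)
        f2 = np.where(depth > 0, c2 / depth, 0.0)
        f3 = np.where(depth > 0, c3 / depth, 0.0)

    calls = np.full(n, "N", dtype="<U1")
    depth_ok = (depth >= params.min_depth) & \
               (depth <= params.max_depth_factor * sample_median_depth)
    hom = depth_ok & (f1 >= params.hom_fraction)
    het = depth_ok & ~hom & (f2 >= params.het_fraction) & \
        (f3 < params.het_fraction)
    bases = np.array(list(BASE_ORDER))
    calls[hom] = bases[top1[hom]]
    if het.any():
        # alphabetical ordering of the pair; argsort stability breaks
        # exact count ties towards the lower base index already
        lo = np.minimum(top1[het], top2[het])
        hi = np.maximum(top1[het], top2[het])
        codes = np.array([[IUPAC_CODE[frozenset((BASE_ORDER[i], BASE_ORDER[j]))]
                           if i != j else "N"
                           for j in range(4)] for i in range(4)])
        calls[het] = codes[lo, hi]
    return calls


def call_pileup(pileup: pd.DataFrame, sample_median_depth: float | None = None,
                params: CallParams = CallParams()) -> pd.DataFrame:
    """Call every site of a pileup table.

    Returns a frame with chrom, pos, ref, call.  The median depth
    defaults to the median of the table's depth column (the isolate's
    sequencing depth).
    """
    if sample_median_depth is None:
        sample_median_depth = float(pileup["depth"].median())
    counts = pileup[COUNT_COLS].to_numpy()
    calls = call_genotypes_vector(counts, pileup["depth"].to_numpy(),
                                  sample_median_depth, params)
    return pd.DataFrame({"chrom": pileup["chrom"], "pos": pileup["pos"],
                         "ref": pileup["ref"], "call": calls})


# ---------------------------------------------------------------------------
# matrix


@dataclass
class GenotypeMatrix:
    """Isolates x variant sites, IUPAC-encoded.

    ``calls`` has shape (n_isolates, n_sites) over the alphabet
    {A,C,G,T} ∪ {R,Y,S,W,K,M} ∪ {N}; sites are ordered by (chrom, pos)
    in the chromosome order of first appearance.
    """

    isolates: list[str]
    chrom: np.ndarray       # per-site chromosome name
    pos: np.ndarray         # per-site 1-based position
    ref: np.ndarray         # per-site reference base
    calls: np.ndarray       # (n_isolates, n_sites) '<U1'

    @property
    def n_sites(self) -> int:
        return self.pos.size

    def row(self, isolate: str) -> np.ndarray:
        return self.calls[self.isolates.index(isolate)]

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == "N").mean(axis=0)

    def subset(self, isolates: list[str]) -> "GenotypeMatrix":
        idx = [self.isolates.index(i) for i in isolates]
        return GenotypeMatrix(list(isolates), self.chrom, self.pos, self.ref,
                              self.calls[idx])

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_arrays([self.chrom, self.pos],
                                         names=["chrom", "pos"])
        return pd.DataFrame(self.calls, index=self.isolates, columns=cols)

    def to_tsv(self, handle: IO[str]) -> None:
        handle.write("isolate\t" + "\t".join(
            f"{c}:{p}:{r}" for c, p, r in zip(self.chrom, self.pos, self.ref))
            + "\n")
        for i, iid in enumerate(self.isolates):
            handle.write(iid + "\t" + "\t".join(self.calls[i]) + "\n")

    @classmethod
    def from_tsv(cls, handle: IO[str]) -> "GenotypeMatrix":
        header = handle.readline().rstrip("\n").split("\t")[1:]
        chrom, pos, ref = [], [], []
        for key in header:
            c, p, r = key.rsplit(":", 2)
            chrom.append(c); pos.append(int(p)); ref.append(r)
        isolates, rows = [], []
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            isolates.append(parts[0])
            rows.append(parts[1:])
        return cls(isolates, np.array(chrom), np.array(pos, dtype=np.int64),
                   np.array(ref), np.array(rows, dtype="<U1"))


def build_matrix(calls: Mapping[str, pd.DataFrame],
                 max_site_missing_fraction: float = 0.10) -> GenotypeMatrix:
    """Assemble per-isolate call tables into a variant-site matrix.

    Sites are retained when at least one call differs from the
    reference or from another isolate, and the per-site missing (N)
    fraction does not exceed the threshold (default 10%).
    """
    if not isinstance(calls, Mapping):
        pairs = list(calls)
        ids = [iid for iid, _ in pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate isolate id")
        calls = dict(pairs)
    isolates = list(calls)
    first = calls[isolates[0]]
    chrom = first["chrom"].to_numpy()
    pos = first["pos"].to_numpy()
    ref = first["ref"].to_numpy()
    mat = np.empty((len(isolates), pos.size), dtype="<U1")
    for i, iid in enumerate(isolates):
        df = calls[iid]
        if df.shape[0] != pos.size or not (
                np.array_equal(df["pos"].to_numpy(), pos)
                and np.array_equal(df["chrom"].to_numpy(), chrom)):
            raise ValueError(f"isolate {iid} not on the shared coordinate system")
        mat[i] = df["call"].to_numpy()
    non_n = mat != "N"
    differs_ref = non_n & (mat != ref[None, :])
    variant = differs_ref.any(axis=0)
    missing_ok = (~non_n).mean(axis=0) <= max_site_missing_fraction
    keep = variant & missing_ok & non_n.any(axis=0)
    return GenotypeMatrix(isolates, chrom[keep], pos[keep], ref[keep],
                          mat[:, keep])


def heterozygosity(calls: np.ndarray | pd.Series,
                   callable_site_count: int | None = None) -> float:
    """Ratio of heterozygous calls to callable (non-N) sites.

    The denominator stands in for the isolate's consensus genome size:
    by default it is the number of non-N calls in the input, which
    should be the whole-genome call vector, not the variant-site matrix
    row.
    """
    arr = np.asarray(calls)
    n_het = int(np.isin(arr, list(HET_CODES)).sum())
    if callable_site_count is None:
        callable_site_count = int((arr != "N").sum())
    if callable_site_count <= 0:
        raise ValueError("callable site count must be positive")
    return n_het / callable_site_count


def heterozygosity_table(calls: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    rows = []
    for iid, df in calls.items():
        arr = df["call"].to_numpy()
        rows.append({"isolate": iid,
                     "n_het": int(np.isin(arr, list(HET_CODES)).sum()),
                     "callable_sites": int((arr != "N").sum())})
    out = pd.DataFrame(rows)
    out["heterozygosity"] = out["n_het"] / out["callable_sites"]
    return out


# ---------------------------------------------------------------------------
# VCF export


def export_vcf(matrix: GenotypeMatrix, handle: IO[str],
               contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write the matrix as VCF v4.2 with diploid GT fields.

    Het IUPAC codes expand to the two encoded alleles; hom-alt becomes
    1/1 (or the matching ALT index); N becomes ./. .  Multi-allelic
    sites list every non-reference allele observed in the cohort.
    """
    if matrix.n_sites == 0:
        raise ValueError("cannot export an empty matrix")
    handle.write("##fileformat=VCFv4.2\n")
    handle.write("##source=saccpop\n")
    for c in dict.fromkeys(matrix.chrom.tolist()):
        if contig_lengths and c in contig_lengths:
            handle.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
        else:
            handle.write(f"##contig=<ID={c}>\n")
    handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.isolates) + "\n")
    for j in range(matrix.n_sites):
        ref = matrix.ref[j]
        col = matrix.calls[:, j]
        alts: list[str] = []
        for call in col:
            if call == "N":
                continue
            for allele in expand_call(call):
                if allele != ref and allele not in alts:
                    alts.append(allele)
        allele_index = {ref: 0, **{a: k + 1 for k, a in enumerate(alts)}}
        gts = []
        for call in col:
            if call == "N":
                gts.append("./.")
            else:
                a, b = expand_call(call)
                gts.append(f"{allele_index[a]}/{allele_index[b]}")
        handle.write(f"{matrix.chrom[j]}\t{matrix.pos[j]}\t.\t{ref}\t"
                     f"{','.join(alts) if alts else '.'}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def matrix_from_vcf(path: str) -> GenotypeMatrix:
    """Read a saccpop-style VCF back into a genotype matrix (round trip)."""
    import pysam

    vf = pysam.VariantFile(path)
    isolates = list(vf.header.samples)
    chrom, pos, ref, cols = [], [], [], []
    for rec in vf:
        alleles = [rec.ref] + [a for a in (rec.alts or ())]
        col = []
        for iid in isolates:
            gt = rec.samples[iid]["GT"]
            if gt is None or None in gt:
                col.append("N")
            else:
                a, b = sorted(alleles[i] for i in gt)
                col.append(a if a == b else IUPAC_CODE[frozenset((a, b))])
        chrom.append(rec.chrom); pos.append(rec.pos); ref.append(rec.ref)
        cols.append(col)
    calls = np.array(cols, dtype="<U1").T if cols else \
        np.empty((len(isolates), 0), dtype="<U1")
    return GenotypeMatrix(isolates, np.array(chrom),
                          np.array(pos, dtype=np.int64), np.array(ref), calls)
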