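"""Four-step diagnostic variant prioritization with pedigree co-segregation.

The filter cascade mirrors clinical targeted-panel triage:

1. basic      — site depth >= 8x and Phred-like quality >= 30;
2. frequency  — every recorded population allele frequency <= 0.05
                (absent = unobserved = 0, so novel variants survive);
3. region     — intronic/UTR/synonymous changes are discarded unless they are
                splice-site changes or catalogued disease mutations (HGMD);
4. segregation — at least one inheritance model (autosomal recessive,
                X-linked, de novo, dominant) fits every typed family member.

Survivors are classified Pathogenic (change matches a curated known-pathogenic
set), Likely pathogenic (novel protein-truncating with consistent
segregation), or VUS. Thresholds are kept-if-at-boundary: the cascade
excludes strictly-below-threshold records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CONSEQUENCES = {
    "missense", "nonsense", "frameshift", "inframe_indel",
    "splice_site", "synonymous", "intronic", "utr",
}
TRUNCATING = {"nonsense", "frameshift"}
NONCODING = {"intronic", "utr", "synonymous"}
GENOTYPES = {"hom_ref", "het", "hom_alt", "hemi"}
CARRIER = {"het", "hom_alt", "hemi"}


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    depth: int
    gene: str
    consequence: str
    af: dict[str, float] = field(default_factory=dict)
    hgmd: bool = False
    genotypes: dict[str, str] = field(default_factory=dict)
    hgvs_c: str = ""
    hgvs_p: str = ""

    def __post_init__(self) -> None:
        if self.qual < 0 or self.depth < 0:
            raise ValueError("qual and depth must be non-negative")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        for db, f in self.af.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"allele frequency {f} for {db} outside [0, 1]")
        for person, gt in self.genotypes.items():
            if gt not in GENOTYPES:
                raise ValueError(f"unknown genotype {gt!r} for {person}")

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass
class PedMember:
    sex: str  # "male" | "female" | "unknown"
    affected: bool
    father: str | None = None
    mother: str | None = None


@dataclass
class Pedigree:
    members: dict[str, PedMember]
    proband: str

    def __post_init__(self) -> None:
        if self.proband not in self.members:
            raise ValueError(f"proband {self.proband!r} is not a pedigree member")
        for pid, m in self.members.items():
            for parent in (m.father, m.mother):
                if parent is not None and parent not in self.members:
                    raise ValueError(f"parent {parent!r} of {pid!r} is not a member")


@dataclass
class TriageResult:
    variant: VariantRecord
    step_passed: dict[str, bool]
    classification: str  # Pathogenic | Likely pathogenic | VUS | excluded
    origin: str
    reasons: list[str]


# ---------------------------------------------------------------------------
# Steps 1-3: pure, order-independent predicates


def basic_filter(v: VariantRecord, min_depth: int = 8, min_qual: float = 30) -> bool:
    """Keep variants with adequate coverage and call quality (boundaries kept)."""
    return v.depth >= min_depth and v.qual >= min_qual


def frequency_filter(v: VariantRecord, cutoff: float = 0.05) -> bool:
    """Keep variants rare in every recorded population database."""
    return all(f <= cutoff for f in v.af.values())


def region_filter(v: VariantRecord) -> bool:
    """Discard intronic/UTR/synonymous changes unless splice-site or in HGMD."""
    if v.consequence == "splice_site":
        return True
    return v.consequence not in NONCODING or v.hgmd


# ---------------------------------------------------------------------------
# Step 4: co-segregation


def _typed(v: VariantRecord, person: str | None) -> bool:
    return person is not None and person in v.genotypes


def _carries(v: VariantRecord, person: str) -> bool:
    return v.genotypes.get(person) in CARRIER


def _x_copies(person: str, ped: Pedigree, proband_karyotype: str | None) -> int:
    """Effective X-chromosome copy count, preferring the dosage karyotype
    for the proband over reported sex."""
    if person == ped.proband and proband_karyotype:
        return proband_karyotype.count("X")
    return 1 if ped.members[person].sex == "male" else 2


def _fits_de_novo(v: VariantRecord, ped: Pedigree) -> bool:
    p = ped.members[ped.proband]
    if not (_typed(v, p.father) and _typed(v, p.mother)):
        return False
    return (
        _carries(v, ped.proband)
        and v.genotypes[p.father] == "hom_ref"
        and v.genotypes[p.mother] == "hom_ref"
    )


def _fits_recessive(v: VariantRecord, ped: Pedigree) -> bool:
    ok = False
    for pid, m in ped.members.items():
        if pid not in v.genotypes:
            continue
        gt = v.genotypes[pid]
        if m.affected:
            if gt != "hom_alt":
                return False
            ok = True
        elif gt == "hom_alt":
            return False
    p = ped.members[ped.proband]
    for parent in (p.father, p.mother):
        if _typed(v, parent) and v.genotypes[parent] not in ("het",):
            return False
    return ok


def _fits_x_linked(v: VariantRecord, ped: Pedigree, karyotype: str | None) -> bool:
    if v.chrom not in ("chrX", "X"):
        return False
    ok = False
    for pid, m in ped.members.items():
        if pid not in v.genotypes:
            continue
        gt = v.genotypes[pid]
        one_x = _x_copies(pid, ped, karyotype) == 1
        if m.affected:
            if one_x and gt != "hemi":
                return False
            if not one_x and gt not in ("het", "hom_alt"):
                return False
            ok = True
        else:
            if one_x and gt == "hemi":
                return False
            if not one_x and gt == "hom_alt":
                return False
    p = ped.members[ped.proband]
    # source of the allele: a carrier mother, or de novo (both parents clear)
    if _typed(v, p.mother):
        if not (_carries(v, p.mother) or _fits_de_novo(v, ped)):
            return False
    if _typed(v, p.father) and v.genotypes[p.father] == "hemi" and not ped.members[p.father].affected:
        return False
    return ok


def _fits_dominant(v: VariantRecord, ped: Pedigree) -> bool:
    ok = False
    for pid, m in ped.members.items():
        if pid not in v.genotypes:
            continue
        carries = _carries(v, pid)
        if m.affected and not carries:
            return False
        if not m.affected and carries:
            return False
        if m.affected:
            ok = True
    return ok


def infer_origin(v: VariantRecord, ped: Pedigree) -> str:
    p = ped.members[ped.proband]
    father_typed, mother_typed = _typed(v, p.father), _typed(v, p.mother)
    if not father_typed and not mother_typed:
        return "untyped"
    mat = mother_typed and _carries(v, p.mother)
    pat = father_typed and _carries(v, p.father)
    if mat and not pat:
        return "mat"
    if pat and not mat:
        return "pat"
    if not mat and not pat and father_typed and mother_typed and _carries(v, ped.proband):
        return "de novo"
    if mat and pat:
        return "biparental"
    return "untyped"


def segregation_filter(
    v: VariantRecord, ped: Pedigree, karyotype_label: str | None = None
) -> tuple[bool, str]:
    """True iff some inheritance model fits all typed members; also reports
    the allele's parental origin (mat / pat / de novo / untyped).

    X-linked hemizygosity is judged from the dosage karyotype when given, not
    from reported sex: a 46,XY phenotypic female is genetically hemizygous.
    """
    if ped.proband not in v.genotypes:
        raise ValueError(f"proband genotype missing for variant {v.locus}")
    fits = (
        _fits_recessive(v, ped)
        or _fits_x_linked(v, ped, karyotype_label)
        or _fits_de_novo(v, ped)
        or _fits_dominant(v, ped)
    )
    return fits, infer_origin(v, ped)


def compound_het_pairs(
    variants: list[VariantRecord], ped: Pedigree
) -> list[tuple[VariantRecord, VariantRecord]]:
    """Candidate compound-heterozygote pairs: two surviving proband-het
    variants in one gene (phase unknown; trans-configuration is required only
    when both parents are typed)."""
    p = ped.members[ped.proband]
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in variants:
        if v.genotypes.get(ped.proband) == "het":
            by_gene.setdefault(v.gene, []).append(v)
    pairs = []
    for gene_vars in by_gene.values():
        for i in range(len(gene_vars)):
            for j in range(i + 1, len(gene_vars)):
                a, b = gene_vars[i], gene_vars[j]
                if _typed(a, p.father) and _typed(a, p.mother) and _typed(b, p.father) and _typed(b, p.mother):
                    oa, ob = infer_origin(a, ped), infer_origin(b, ped)
                    if {oa, ob} != {"mat", "pat"}:
                        continue
                pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# Classification and orchestration


def triage_classify(
    v: VariantRecord, origin: str, known_db: set[str]
) -> str:
    """Three-way surrogate classification of a variant that survived all steps.

    Pathogenic when the nucleotide or protein change matches the curated
    known-pathogenic set; else Likely pathogenic for novel protein-truncating
    changes with consistent segregation; else VUS.
    """
    if (v.hgvs_c and v.hgvs_c in known_db) or (v.hgvs_p and v.hgvs_p in known_db):
        return "Pathogenic"
    if v.consequence in TRUNCATING:
        return "Likely pathogenic"
    return "VUS"


def triage_variant(
    v: VariantRecord,
    ped: Pedigree,
    known_db: set[str] | None = None,
    karyotype_label: str | None = None,
    min_depth: int = 8,
    min_qual: float = 30,
    af_cutoff: float = 0.05,
) -> TriageResult:
    """Run the four-step cascade on one variant and classify survivors."""
    steps: dict[str, bool] = {}
    reasons: list[str] = []
    steps["basic"] = basic_filter(v, min_depth=min_depth, min_qual=min_qual)
    if not steps["basic"]:
        reasons.append(f"depth {v.depth} or quality {v.qual:g} below threshold")
    steps["frequency"] = frequency_filter(v, cutoff=af_cutoff)
    if not steps["frequency"]:
        worst = max(v.af, key=v.af.get)
        reasons.append(f"allele frequency {v.af[worst]:g} in {worst} exceeds {af_cutoff:g}")
    steps["region"] = region_filter(v)
    if not steps["region"]:
        reasons.append(f"{v.consequence} outside coding/splice regions, not in HGMD")
    origin = "untyped"
    if all(steps.values()):
        seg, origin = segregation_filter(v, ped, karyotype_label)
        steps["segregation"] = seg
        if not seg:
            reasons.append("no inheritance model fits the typed family members")
    else:
        steps["segregation"] = False
        reasons.append("segregation not assessed (earlier step failed)")
    if all(steps.values()):
        classification = triage_classify(v, origin, known_db or set())
        reasons.append(f"classified {classification} (origin {origin})")
    else:
        classification = "excluded"
    return TriageResult(variant=v, step_passed=steps, classification=classification,
                        origin=origin, reasons=reasons)


def percent(numerator: int, denominator: int) -> float:
    """Rate as a percentage rounded to one decimal (e.g. 8/21 -> 38.1)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, 1)


def cohort_summary(classifications: list[str]) -> dict[str, float | int]:
    """Counts and rates of a cohort's best per-proband classifications."""
    n = len(classifications)
    counts = {k: classifications.count(k) for k in ("Pathogenic", "Likely pathogenic", "VUS")}
    return {
        "n_probands": n,
        **counts,
        "pathogenic_rate": percent(counts["Pathogenic"], n),
        "likely_pathogenic_rate": percent(counts["Likely pathogenic"], n),
        "vus_rate": percent(counts["VUS"], n),
        "diagnostic_yield": percent(counts["Pathogenic"] + counts["Likely pathogenic"], n),
    }


# ---------------------------------------------------------------------------
# File interfaces: VCF (cyvcf2), 6-column PED, known_db TSV, triage report


_GT_NAMES = {0: "hom_ref", 1: "het", 3: "hom_alt"}


def read_vcf(path: str) -> list[VariantRecord]:
    """Read an annotated VCF subset (INFO keys DP, GENE, CSQ, AF_*, HGMD)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    out = []
    for var in vcf:
        af = {}
        for key, val in var.INFO:
            if key.startswith("AF_"):
                af[key[3:]] = float(val)
        genotypes = {}
        for s, entry, gt_type in zip(samples, var.genotypes, var.gt_types):
            alleles = entry[:-1]
            if len(alleles) == 1:  # haploid call
                if alleles[0] < 0:
                    continue
                genotypes[s] = "hemi" if alleles[0] > 0 else "hom_ref"
            elif gt_type in _GT_NAMES:
                genotypes[s] = _GT_NAMES[gt_type]
        out.append(
            VariantRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=var.ALT[0] if var.ALT else ".",
                qual=float(var.QUAL or 0.0),
                depth=int(var.INFO.get("DP", 0)),
                gene=str(var.INFO.get("GENE", "")),
                consequence=str(var.INFO.get("CSQ", "missense")),
                af=af,
                hgmd=bool(var.INFO.get("HGMD", False)),
                genotypes=genotypes,
                hgvs_c=str(var.INFO.get("HGVSC", "") or ""),
                hgvs_p=str(var.INFO.get("HGVSP", "") or ""),
            )
        )
    return out


def read_ped(path: str, proband: str | None = None) -> Pedigree:
    """Read a 6-column PED file; the proband defaults to the first affected member."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["fam", "id", "father", "mother", "sex", "phenotype"],
                     dtype=str)
    members = {}
    first_affected = None
    for r in df.itertuples(index=False):
        affected = str(r.phenotype) == "2"
        members[r.id] = PedMember(
            sex={"1": "male", "2": "female"}.get(str(r.sex), "unknown"),
            affected=affected,
            father=None if r.father in ("0", None) else r.father,
            mother=None if r.mother in ("0", None) else r.mother,
        )
        if affected and first_affected is None:
            first_affected = r.id
    return Pedigree(members=members, proband=proband or first_affected or next(iter(members)))


def read_known_db(path: str) -> set[str]:
    """Known-pathogenic changes from a (gene, hgvs_c, hgvs_p) TSV."""
    df = pd.read_csv(path, sep="\t")
    known: set[str] = set()
    for col in ("hgvs_c", "hgvs_p"):
        if col in df.columns:
            known |= set(df[col].dropna().astype(str)) - {"", "."}
    return known


def write_triage_tsv(results: list[TriageResult], path: str) -> None:
    rows = []
    for r in results:
        for step, passed in r.step_passed.items():
            rows.append({
                "locus": r.variant.locus, "gene": r.variant.gene,
                "hgvs_c": r.variant.hgvs_c, "step": step, "passed": passed,
                "classification": r.classification, "origin": r.origin,
                "reasons": "; ".join(r.reasons),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
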