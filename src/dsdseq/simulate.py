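"""Seeded synthetic-cohort generator with known ground truth.

Emulates every input the pipeline consumes at the count level (no reads):
per-window depths with multiplicative GC bias and negative-binomial
overdispersion, whole-sex-chromosome copy states (XX/XY/XXY/XO/...),
embedded CNVs, per-base SRY coverage, and annotated variant tables with
pedigree genotypes.

Study-condition defaults: mean autosomal depth 300x, NB size 30, GC bias
exp(1.0 * (gc - 0.5)) (a monotone ~±28 % swing over the panel GC range), and
per-chromosome capture efficiencies chrX 1.02 / chrY 0.832 chosen so that
default simulations land on the empirical dosage centroids used by the
classifier (one Y copy ~= 0.416 of the autosomal baseline).

The toy panel spans a fictitious mini-genome (coordinates < 10 Mb) so
fixtures stay tiny; its geometry (40 chrX marker genes, 6 chrY marker genes)
matches the real panel's sex-marker design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gcnorm import DepthMatrix
from .regions import GenomicInterval, Panel, Window, make_windows
from .varfilter import PedMember, Pedigree, VariantRecord

DEFAULT_MEAN_DEPTH = 300.0
DEFAULT_NB_SIZE = 30.0
DEFAULT_GC_BETA = 1.0
DEFAULT_CAPTURE_EFFICIENCY = {"chrX": 1.02, "chrY": 0.832}
COHORT_45 = [("XX", 17), ("XY", 24), ("XXY", 3), ("XO", 1)]

_PANEL_GC_SEED = 20160330  # fixed: panel GC is a property of the design, not of a run


@dataclass
class SimConfig:
    seed: int
    karyotypes: dict[str, str]
    panel: Panel | None = None
    windows: list[Window] | None = None
    mean_depth: float = DEFAULT_MEAN_DEPTH
    nb_size: float = DEFAULT_NB_SIZE
    gc_beta: float = DEFAULT_GC_BETA
    capture_efficiency: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CAPTURE_EFFICIENCY)
    )
    cnvs: list[tuple[str, GenomicInterval, int]] = field(default_factory=list)
    sry_positive: set[str] = field(default_factory=set)
    # per-window capture efficiency (probe-level variation shared by all
    # samples); None = lognormal draw from a fixed panel-design stream
    window_efficiency: np.ndarray | None = None
    window_efficiency_sigma: float = 0.35


def gc_bias(gc: np.ndarray, beta: float = DEFAULT_GC_BETA) -> np.ndarray:
    """Monotone multiplicative GC bias, exp(beta * (gc - 0.5))."""
    return np.exp(beta * (np.asarray(gc, dtype=float) - 0.5))


def toy_panel(
    n_autosomal_targets: int = 60,
    n_x_genes: int = 40,
    n_y_genes: int = 6,
    target_len: int = 200,
    marker_len: int = 155,
) -> tuple[Panel, list[Window]]:
    """Deterministic toy capture panel over a fictitious mini-genome.

    Autosomal targets are spread over chr1-chr6; each chrX/chrY marker gene
    gets one target. Window GC fractions are drawn once from a fixed stream
    (the panel design is constant across simulation runs).
    """
    targets: list[GenomicInterval] = []
    gene_of: dict[int, str] = {}
    autos = [f"chr{c}" for c in range(1, 7)]
    for i in range(n_autosomal_targets):
        chrom = autos[i % len(autos)]
        start = 100_000 + (i // len(autos)) * 10_000
        targets.append(GenomicInterval(chrom, start, start + target_len))
        gene_of[len(targets) - 1] = f"AUTO{i + 1}"
    x_markers = {f"XGENE{i + 1}" for i in range(n_x_genes)}
    for i in range(n_x_genes):
        start = 200_000 + i * 10_000
        targets.append(GenomicInterval("chrX", start, start + marker_len))
        gene_of[len(targets) - 1] = f"XGENE{i + 1}"
    y_markers = {f"YGENE{i + 1}" for i in range(n_y_genes)}
    for i in range(n_y_genes):
        start = 300_000 + i * 10_000
        targets.append(GenomicInterval("chrY", start, start + marker_len))
        gene_of[len(targets) - 1] = f"YGENE{i + 1}"
    panel = Panel(targets=targets, gene_of=gene_of, x_markers=x_markers, y_markers=y_markers)
    bare = []
    for i, t in enumerate(panel.targets):
        bare.extend(make_windows(t, origin_target=i))
    rng = np.random.default_rng(_PANEL_GC_SEED)
    gcs = rng.uniform(0.25, 0.75, size=len(bare))
    windows = [Window(w.interval, gc=float(g), origin_target=w.origin_target)
               for w, g in zip(bare, gcs)]
    return panel, windows


def _copies(karyotype: str, chrom: str) -> int:
    if chrom in ("chrX", "X"):
        return karyotype.count("X")
    if chrom in ("chrY", "Y"):
        return karyotype.count("Y")
    return 2


def simulate_depth(config: SimConfig) -> tuple[DepthMatrix, dict]:
    """Draw a raw depth matrix: NB(mean_depth * copies/2 * gc_bias * capture_eff, nb_size).

    Returns the matrix plus a truth record with every per-window copy state.
    """
    if config.panel is None or config.windows is None:
        panel, windows = toy_panel()
    else:
        panel, windows = config.panel, config.windows
    rng = np.random.default_rng(config.seed)
    samples = list(config.karyotypes)
    gc = np.array([w.gc for w in windows])
    bias = gc_bias(gc, config.gc_beta)
    eff = np.array([config.capture_efficiency.get(w.interval.chrom, 1.0) for w in windows])
    if config.window_efficiency is not None:
        win_eff = np.asarray(config.window_efficiency, dtype=float)
    else:
        panel_rng = np.random.default_rng(_PANEL_GC_SEED + 1)
        win_eff = panel_rng.lognormal(mean=0.0, sigma=config.window_efficiency_sigma,
                                      size=len(windows))
    eff = eff * win_eff
    copies = np.empty((len(samples), len(windows)), dtype=float)
    for si, s in enumerate(samples):
        karyo = config.karyotypes[s]
        copies[si] = [_copies(karyo, w.interval.chrom) for w in windows]
        for cnv_sample, iv, cn in config.cnvs:
            if cnv_sample != s:
                continue
            for wi, w in enumerate(windows):
                if (w.interval.chrom == iv.chrom
                        and w.interval.start < iv.end and iv.start < w.interval.end):
                    copies[si, wi] = cn
    mu = config.mean_depth * (copies / 2.0) * bias[None, :] * eff[None, :]
    size = config.nb_size
    counts = np.zeros(mu.shape)
    pos = mu > 0
    counts[pos] = rng.negative_binomial(n=size, p=size / (size + mu[pos]))
    dm = DepthMatrix(samples=samples, windows=windows, raw=counts)
    truth = {
        "karyotypes": dict(config.karyotypes),
        "copies": {s: copies[si].astype(int).tolist() for si, s in enumerate(samples)},
        "cnvs": [(s, str(iv), cn) for s, iv, cn in config.cnvs],
    }
    return dm, truth


def simulate_cohort_45(seed: int = 1, **overrides) -> tuple[DepthMatrix, dict]:
    """The 45-sample sex-dosage validation cohort: 17 XX, 24 XY, 3 XXY, 1 XO."""
    karyotypes: dict[str, str] = {}
    i = 1
    for label, n in COHORT_45:
        for _ in range(n):
            karyotypes[f"S{i:02d}"] = label
            i += 1
    config = SimConfig(seed=seed, karyotypes=karyotypes, **overrides)
    return simulate_depth(config)


def simulate_sry_depths(
    positive: bool, seed: int, length: int = 735, mean_depth: float = 120.0, noise_rate: float = 0.5
) -> np.ndarray:
    """Per-base depth over the SRY target for an XX sample.

    Positive samples carry the translocated gene at full capture depth;
    negative samples show only sparse sub-1x mismapping noise.
    """
    rng = np.random.default_rng(seed)
    if positive:
        return rng.poisson(mean_depth, size=length).astype(float)
    return (rng.random(length) < noise_rate / mean_depth).astype(float)


# ---------------------------------------------------------------------------
# Variant-table scenarios


def _trio_ped(proband: str, sex: str, extra_affected_sib: str | None = None) -> Pedigree:
    members = {
        f"{proband}-F": PedMember(sex="male", affected=False),
        f"{proband}-M": PedMember(sex="female", affected=False),
        proband: PedMember(sex=sex, affected=True,
                           father=f"{proband}-F", mother=f"{proband}-M"),
    }
    if extra_affected_sib:
        members[extra_affected_sib] = PedMember(
            sex=sex, affected=True, father=f"{proband}-F", mother=f"{proband}-M"
        )
    return Pedigree(members=members, proband=proband)


def _noise_variant(pos: int, proband: str, ped: Pedigree) -> VariantRecord:
    gts = {m: "het" for m in ped.members}
    return VariantRecord(
        chrom="chr2", pos=pos, ref="G", alt="T", qual=60, depth=90,
        gene="NOISEGENE", consequence="missense", af={"1000G": 0.2},
        genotypes=gts, hgvs_c=f"c.{pos}G>T",
    )


def simulate_variants(scenario: str, seed: int = 1) -> tuple[list[VariantRecord], Pedigree, dict]:
    """Annotated variants + pedigree for a named family scenario.

    ``xlinked_brothers``: two affected brothers hemizygous for an X-linked
    missense change, mother het, father clear (maternal origin).
    ``de_novo``: a truncating change hemizygous in the proband, absent from
    both unaffected parents. Both scenarios also carry a common (AF 0.2)
    noise variant that the frequency step must remove.
    """
    if scenario == "xlinked_brothers":
        ped = _trio_ped("P1", "male", extra_affected_sib="P2")
        causal = VariantRecord(
            chrom="chrX", pos=66_941_751, ref="G", alt="A", qual=80, depth=154,
            gene="AR", consequence="missense",
            genotypes={"P1": "hemi", "P2": "hemi", "P1-M": "het", "P1-F": "hom_ref"},
            hgvs_c="c.2158G>A", hgvs_p="p.Ala720Thr",
        )
        truth = {"surviving": ["chrX:66941751"], "origin": "mat", "classification": "VUS"}
    elif scenario == "de_novo":
        ped = _trio_ped("P1", "female")
        causal = VariantRecord(
            chrom="chrY", pos=2_655_030, ref="C", alt="CA", qual=70, depth=127,
            gene="SRY", consequence="frameshift",
            genotypes={"P1": "hemi", "P1-M": "hom_ref", "P1-F": "hom_ref"},
            hgvs_c="c.230_231insA", hgvs_p="p.Lys77fs",
        )
        truth = {"surviving": ["chrY:2655030"], "origin": "de novo",
                 "classification": "Likely pathogenic"}
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    variants = [causal, _noise_variant(10_000 + seed % 1000, "P1", ped)]
    return variants, ped, truth


def simulate_triage_cohort_21(seed: int = 1) -> tuple[list[tuple[list[VariantRecord], Pedigree, str]], set[str]]:
    """A 21-proband triage cohort with known classification truth.

    Composition: 6 probands with catalogued pathogenic changes, 2 with novel
    protein-truncating de novo changes, 3 with novel missense/in-frame
    maternal changes, and 10 whose candidate variants fail a filter step
    (common, non-coding, or non-segregating) and remain undiagnosed.
    """
    known_db = {"c.297+2T>C", "p.Arg787*", "p.Gln59*", "p.Tyr91*", "c.737G>A", "c.680G>A"}
    probands: list[tuple[list[VariantRecord], Pedigree, str]] = []

    def _family(i: int, variant: VariantRecord | None, karyotype: str) -> None:
        name = f"D{i:02d}"
        ped = _trio_ped(name, "male" if karyotype.endswith("Y") else "female")
        vs = []
        if variant is not None:
            vs.append(variant)
        vs.append(_noise_variant(20_000 + i, name, ped))
        probands.append((vs, ped, karyotype))

    known_changes = ["c.297+2T>C", "p.Arg787*", "p.Gln59*", "p.Tyr91*", "c.737G>A", "c.680G>A"]
    for i, change in enumerate(known_changes, start=1):
        name = f"D{i:02d}"
        hgvs_c = change if change.startswith("c.") else f"c.{1000 + i}G>A"
        hgvs_p = change if change.startswith("p.") else ""
        v = VariantRecord(
            chrom="chrX", pos=100_000 + i, ref="G", alt="A", qual=90, depth=150,
            gene=f"GENE{i}", consequence="splice_site" if "+2" in change else "missense",
            genotypes={name: "hemi", f"{name}-M": "het", f"{name}-F": "hom_ref"},
            hgvs_c=hgvs_c, hgvs_p=hgvs_p,
        )
        _family(i, v, "XY")
    for i in (7, 8):  # novel truncating, de novo
        name = f"D{i:02d}"
        v = VariantRecord(
            chrom="chr8", pos=200_000 + i, ref="A", alt="AT" if i == 7 else "T", qual=85, depth=130,
            gene="CHD7", consequence="frameshift" if i == 7 else "nonsense",
            genotypes={name: "het", f"{name}-M": "hom_ref", f"{name}-F": "hom_ref"},
            hgvs_c=f"c.{7000 + i}delA",
        )
        _family(i, v, "XX")
    for i in (9, 10, 11):  # novel missense / in-frame, maternal X-linked
        name = f"D{i:02d}"
        v = VariantRecord(
            chrom="chrX", pos=300_000 + i, ref="A", alt="G", qual=88, depth=120,
            gene="AR", consequence="missense" if i != 11 else "inframe_indel",
            genotypes={name: "hemi", f"{name}-M": "het", f"{name}-F": "hom_ref"},
            hgvs_c=f"c.{1800 + i}A>G",
        )
        _family(i, v, "XY")
    rng = np.random.default_rng(seed)
    for i in range(12, 22):  # unresolved: candidates fail a step
        kind = rng.integers(0, 3)
        name = f"D{i:02d}"
        if kind == 0:  # too common
            v = VariantRecord(chrom="chr3", pos=400_000 + i, ref="C", alt="T", qual=80, depth=100,
                              gene="GENEX", consequence="missense", af={"1000G": 0.12},
                              genotypes={name: "het", f"{name}-M": "het", f"{name}-F": "hom_ref"})
        elif kind == 1:  # non-coding, not catalogued
            v = VariantRecord(chrom="chr3", pos=400_000 + i, ref="C", alt="T", qual=80, depth=100,
                              gene="GENEX", consequence="intronic",
                              genotypes={name: "het", f"{name}-M": "het", f"{name}-F": "hom_ref"})
        else:  # fails co-segregation: unaffected parent carries the same genotype pattern
            v = VariantRecord(chrom="chr3", pos=400_000 + i, ref="C", alt="T", qual=80, depth=100,
                              gene="GENEX", consequence="missense",
                              genotypes={name: "het", f"{name}-M": "het", f"{name}-F": "het"})
        _family(i, v, "XY" if i % 2 else "XX")
    return probands, known_db


# ---------------------------------------------------------------------------
# Writers: VCF v4.2 subset and 6-column PED


_GT_STRINGS = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "hemi": "1"}


def write_vcf(variants: list[VariantRecord], samples: list[str], path: str) -> None:
    chroms = list(dict.fromkeys(v.chrom for v in variants))
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Site read depth">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">',
        '##INFO=<ID=AF_1000G,Number=1,Type=Float,Description="1000 Genomes allele frequency">',
        '##INFO=<ID=AF_INHOUSE,Number=1,Type=Float,Description="In-house allele frequency">',
        '##INFO=<ID=HGMD,Number=0,Type=Flag,Description="Catalogued disease mutation">',
        '##INFO=<ID=HGVSC,Number=1,Type=String,Description="HGVS cDNA change">',
        '##INFO=<ID=HGVSP,Number=1,Type=String,Description="HGVS protein change">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for v in sorted(variants, key=lambda v: (chroms.index(v.chrom), v.pos)):
        info = [f"DP={v.depth}", f"GENE={v.gene}", f"CSQ={v.consequence}"]
        for db, f in v.af.items():
            info.append(f"AF_{db}={f:g}")
        if v.hgmd:
            info.append("HGMD")
        if v.hgvs_c:
            info.append(f"HGVSC={v.hgvs_c}")
        if v.hgvs_p:
            info.append(f"HGVSP={v.hgvs_p}")
        gts = [_GT_STRINGS.get(v.genotypes.get(s, ""), "./.") for s in samples]
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{v.qual:g}\tPASS\t"
            + ";".join(info) + "\tGT\t" + "\t".join(gts)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_ped(ped: Pedigree, path: str, family: str = "FAM1") -> None:
    rows = []
    for pid, m in ped.members.items():
        rows.append("\t".join([
            family, pid, m.father or "0", m.mother or "0",
            {"male": "1", "female": "2"}.get(m.sex, "0"),
            "2" if m.affected else "1",
        ]))
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")
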