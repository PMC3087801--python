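"""Biparental-population GBS read simulator with ground truth.

The generator emulates the study design the pipeline targets: two inbred
parents differing by cut-site presence/absence polymorphism (dominant
tags) and by SNPs inside tag footprints (biallelic tag pairs), crossed
and taken to fully homozygous progeny — doubled haploids from one
meiosis, or recombinant inbred lines modelled as homozygous mosaics with
a doubled effective crossover count.  Each line's expected tag
complement follows from which parent occupies each cut site in its
mosaic, and 86 bp reads are synthesized exactly as the instrument would
deliver them: barcode, CWGC remnant, fragment sequence, read-through
into the common adapter for short fragments, substitution errors,
quality strings, and a sprinkle of adapter-dimer reads.

Defaults reflect the study conditions at desk scale: 43 doubled-haploid
lines, an ApeKI-like cut-site density of one per kilobase, 17% of
fragments shorter than 64 bases, mean depth 5 reads per tag per line,
0.2% substitution error, and an adapter-dimer rate of 0.05% of reads.

Crossover breakpoints are placed uniformly but re-sampled away from any
position within 68 bp of a cut site, so that no tag footprint ever
straddles a parental junction; per-line truth then depends only on which
parent owns each cut site.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .adapters import DEFAULT_KIT
from .barcodes import BarcodeSet, generate_barcode_set
from .digest import reference_tag_loci
from .enzyme import APEKI, RestrictionEnzyme, revcomp
from .mapping import FrameworkMap
from .reads import RawRead
from .tags import TAG_LENGTH, make_tag

_BASES = np.array(list("ACGT"))
# read-through continuation past the far CWG remnant: common adapter,
# then the reverse complement of the primer-2 tail (end of the molecule)
_ADAPTER_CONT = DEFAULT_KIT.common_adapter_top_rest + revcomp(DEFAULT_KIT.pcr2_tail)

READ_LENGTH = 86
_TEMPLATE_LENGTH = READ_LENGTH - 4  # longest read content after the shortest barcode


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    genome_length: int = 200_000
    n_chromosomes: int = 2
    cut_site_density: float = 1 / 1000.0
    site_polymorphism_rate: float = 0.15
    snp_in_tag_rate: float = 0.15
    n_lines: int = 43
    population_type: str = "DH"  # DH | RIL
    crossovers_per_chromosome: float = 2.0
    mean_depth: float = 5.0
    sequencing_error_rate: float = 0.002
    dimer_read_fraction: float = 0.0005
    short_fragment_fraction: float = 0.17
    low_quality_read_fraction: float = 0.02
    base_quality: int = 30
    framework_markers_per_chromosome: int = 25
    marker_error_rate: float = 0.0
    methylation_masked_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rates = dict(site_polymorphism_rate=self.site_polymorphism_rate,
                     snp_in_tag_rate=self.snp_in_tag_rate,
                     sequencing_error_rate=self.sequencing_error_rate,
                     dimer_read_fraction=self.dimer_read_fraction,
                     short_fragment_fraction=self.short_fragment_fraction,
                     low_quality_read_fraction=self.low_quality_read_fraction,
                     marker_error_rate=self.marker_error_rate,
                     methylation_masked_fraction=self.methylation_masked_fraction)
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {r}")
        if self.mean_depth < 0:
            raise SimConfigError("mean_depth must be >= 0")
        if self.population_type not in ("DH", "RIL"):
            raise SimConfigError("population_type must be 'DH' or 'RIL'")
        if self.n_lines < 1 or self.n_chromosomes < 1:
            raise SimConfigError("need at least one line and one chromosome")
        chrom_len = self.genome_length // self.n_chromosomes
        n_sites = max(2, round(chrom_len * self.cut_site_density))
        if chrom_len / n_sites < 400:
            raise SimConfigError(
                "cut_site_density too high to place non-overlapping sites "
                "with clear tag footprints")

    @property
    def chromosome_length(self) -> int:
        return self.genome_length // self.n_chromosomes

    @property
    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def effective_crossovers(self) -> float:
        """Expected crossovers per chromosome in the final homozygous mosaic
        (RILs accumulate roughly twice the single-meiosis map)."""
        scale = 2.0 if self.population_type == "RIL" else 1.0
        return self.crossovers_per_chromosome * scale


@dataclass
class Parents:
    genomes: dict[str, dict[str, str]]  # parent ('A'|'B') -> chrom -> sequence
    sites: pd.DataFrame  # chrom, pos, status in {shared, A_only, B_only}, snp info

    def sites_for(self, parent: str, chrom: str) -> np.ndarray:
        excl = "B_only" if parent == "A" else "A_only"
        sub = self.sites[(self.sites["chrom"] == chrom)
                         & (self.sites["status"] != excl)]
        return np.sort(sub["pos"].to_numpy())


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _destroy_unintended(arr: np.ndarray, intended: set[int],
                        forbidden: set[int], enzyme: RestrictionEnzyme,
                        rng: np.random.Generator) -> None:
    """Mutate bases until the only recognition sites left start at ``intended``.

    Mutations never touch positions inside an intended site span or in
    ``forbidden`` (parent-difference positions that must stay aligned).
    """
    spans = set()
    for p in intended:
        spans.update(range(p, p + len(enzyme.recognition)))
    motif_allowed = [set("G"), set("C"), set("AT"), set("G"), set("C")]
    for _ in range(100):
        stray = [p for p in enzyme.find_sites("".join(arr)) if p not in intended]
        if not stray:
            return
        for p in stray:
            for off in rng.permutation(len(enzyme.recognition)):
                q = p + int(off)
                if q in spans or q in forbidden or q >= len(arr):
                    continue
                choices = [b for b in "ACGT" if b not in motif_allowed[off]]
                arr[q] = choices[rng.integers(0, len(choices))]
                break
            else:
                raise RuntimeError("cannot break stray recognition site")
    raise RuntimeError("stray-site cleanup did not converge")


def _creates_site(arr: np.ndarray, pos: int, enzyme: RestrictionEnzyme,
                  intended: set[int]) -> bool:
    lo = max(0, pos - len(enzyme.recognition) + 1)
    hi = min(len(arr), pos + len(enzyme.recognition))
    window = "".join(arr[lo:hi])
    return any(lo + p not in intended for p in enzyme.find_sites(window))


def simulate_parents(config: SimConfig,
                     rng: np.random.Generator | None = None,
                     enzyme: RestrictionEnzyme = APEKI) -> Parents:
    """Build the two parental genomes and the annotated cut-site table.

    Parent A and parent B are identical random sequences except for (i)
    polymorphic cut sites, ablated in one parent (half in each), and
    (ii) SNPs injected within tag footprints of shared sites with
    sufficiently clear flanks.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    margin = 200
    site_rows = []
    genomes_a: dict[str, str] = {}
    genomes_b: dict[str, str] = {}
    for chrom in config.chromosome_names:
        L = config.chromosome_length
        arr = _random_seq(rng, L)

        n_sites = max(2, round(L * config.cut_site_density))
        n_short = int(round(n_sites * config.short_fragment_fraction))
        n_primary = max(2, n_sites - n_short)
        spacing = (L - 2 * margin) / n_primary
        primaries = np.sort(margin
                            + (np.arange(n_primary) * spacing
                               + rng.uniform(0.1, 0.9, size=n_primary) * spacing
                               ).astype(int))
        hosts = rng.choice(n_primary - 1, size=min(n_short, n_primary - 1),
                           replace=False)
        companions = {int(primaries[h]) + int(rng.integers(20, 60)) for h in hosts}
        positions = sorted(set(primaries.tolist()) | companions)

        if config.methylation_masked_fraction > 0:
            keep = rng.random(len(positions)) >= config.methylation_masked_fraction
            positions = [p for p, k in zip(positions, keep) if k]

        intended = set(positions)
        for p in positions:
            motif = ["G", "C", "A" if rng.random() < 0.5 else "T", "G", "C"]
            arr[p:p + 5] = motif
        _destroy_unintended(arr, intended, set(), enzyme, rng)

        arr_a = arr.copy()
        arr_b = arr.copy()
        diff_positions: set[int] = set()
        pos_sorted = np.array(positions)
        chrom_sites = []
        for idx, p in enumerate(positions):
            status = "shared"
            if rng.random() < config.site_polymorphism_rate:
                status = "A_only" if rng.random() < 0.5 else "B_only"
                target = arr_b if status == "A_only" else arr_a
                target[p + 2] = "C"  # break the W of GCWGC
                diff_positions.add(p + 2)
            chrom_sites.append({"chrom": chrom, "pos": int(p), "status": status,
                                "snp_pos": -1})
        gaps_next = np.diff(np.append(pos_sorted, L))
        gaps_prev = np.diff(np.append(-1, pos_sorted))
        for idx, rec in enumerate(chrom_sites):
            if rec["status"] != "shared":
                continue
            if rng.random() >= config.snp_in_tag_rate:
                continue
            p = rec["pos"]
            sides = []
            if gaps_next[idx] >= 90:
                sides.append("L")
            if gaps_prev[idx] >= 90:
                sides.append("R")
            if not sides:
                continue
            side = sides[int(rng.integers(0, len(sides)))]
            o = int(rng.integers(10, 59))
            snp = p + 1 + o if side == "L" else p + 3 - o
            if not 0 <= snp < L:
                continue
            current = str(arr_b[snp])
            for alt in rng.permutation([b for b in "ACGT" if b != current]):
                arr_b[snp] = alt
                if not _creates_site(arr_b, snp, enzyme, intended):
                    diff_positions.add(snp)
                    rec["snp_pos"] = snp
                    break
                arr_b[snp] = current
        site_rows.extend(chrom_sites)

        for parent_arr, excl in ((arr_a, "B_only"), (arr_b, "A_only")):
            expect = {r["pos"] for r in chrom_sites if r["status"] != excl}
            found = set(enzyme.find_sites("".join(parent_arr)))
            if found != expect:
                raise RuntimeError(
                    f"site bookkeeping failure on {chrom}: "
                    f"{sorted(found ^ expect)[:5]} ...")
        genomes_a[chrom] = "".join(arr_a)
        genomes_b[chrom] = "".join(arr_b)

    sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "status", "snp_pos"])
    return Parents({"A": genomes_a, "B": genomes_b}, sites)


@dataclass
class Population:
    config: SimConfig
    parents: Parents
    lines: list[str]
    phase0: dict[tuple[str, str], str]  # (line, chrom) -> starting parent
    breakpoints: dict[tuple[str, str], np.ndarray]
    framework: FrameworkMap

    def parent_at(self, line: str, chrom: str, pos: int) -> str:
        bps = self.breakpoints[(line, chrom)]
        flips = int(np.searchsorted(bps, pos, side="right"))
        start = self.phase0[(line, chrom)]
        if flips % 2 == 0:
            return start
        return "B" if start == "A" else "A"

    def line_genome(self, line: str) -> dict[str, str]:
        """Materialize the homozygous mosaic sequence of one line."""
        out = {}
        for chrom in self.config.chromosome_names:
            bps = self.breakpoints[(line, chrom)].tolist()
            bounds = [0] + bps + [self.config.chromosome_length]
            parent = self.phase0[(line, chrom)]
            parts = []
            for a, b in zip(bounds, bounds[1:]):
                parts.append(self.parents.genomes[parent][chrom][a:b])
                parent = "B" if parent == "A" else "A"
            out[chrom] = "".join(parts)
        return out


@dataclass
class SimTruth:
    tags: pd.DataFrame      # index: tag sequence; chrom, position, strand, source, segregating
    presence: pd.DataFrame  # expected presence, tags x lines (bool)
    templates: dict[str, str] = field(repr=False, default_factory=dict)

    @property
    def segregating(self) -> pd.Index:
        return self.tags.index[self.tags["segregating"]]


def _tag_records(parents: Parents, enzyme: RestrictionEnzyme) -> dict[str, dict]:
    """tag sequence -> {loci: set, parents: set, template: str}"""
    records: dict[str, dict] = {}
    off = enzyme.cut_offset_top
    rem = len(enzyme.remnant) - 1
    for parent in ("A", "B"):
        for chrom, seq in parents.genomes[parent].items():
            cuts = [s + off for s in enzyme.find_sites(seq)]
            for c1, c2 in zip(cuts, cuts[1:]):
                window = seq[c1:c2 + rem]
                for flank, cut, content in (("L", c1, window),
                                            ("R", c2, revcomp(window))):
                    tag = make_tag(content[:TAG_LENGTH]).sequence
                    template = (content + _ADAPTER_CONT)[:_TEMPLATE_LENGTH]
                    rec = records.setdefault(
                        tag, {"loci": set(), "parents": set(), "template": template})
                    rec["loci"].add((chrom, cut, "+" if flank == "L" else "-"))
                    rec["parents"].add(parent)
    return records


def build_truth(parents: Parents, population: Population,
                enzyme: RestrictionEnzyme = APEKI) -> SimTruth:
    """Expected tags and their per-line presence, derived from the parental
    digests and the lines' crossover mosaics (never from digesting line
    genomes, so digest-based checks remain independent)."""
    records = _tag_records(parents, enzyme)
    rows, presence_rows, templates = [], [], {}
    lines = population.lines
    for tag, rec in sorted(records.items()):
        if len(rec["loci"]) != 1:
            continue  # repeated tags cannot be anchored or scored
        chrom, cut, strand = next(iter(rec["loci"]))
        source = "both" if rec["parents"] == {"A", "B"} else next(iter(rec["parents"]))
        rows.append({"tag": tag, "chrom": chrom, "position": cut, "strand": strand,
                     "source": source, "segregating": source != "both"})
        if source == "both":
            presence_rows.append([True] * len(lines))
        else:
            presence_rows.append([population.parent_at(ln, chrom, cut) == source
                                  for ln in lines])
        templates[tag] = rec["template"]
    tags = pd.DataFrame(rows).set_index("tag")
    presence = pd.DataFrame(presence_rows, index=tags.index, columns=lines)
    return SimTruth(tags, presence, templates)


def simulate_population(parents: Parents, config: SimConfig,
                        rng: np.random.Generator | None = None,
                        enzyme: RestrictionEnzyme = APEKI,
                        ) -> tuple[Population, SimTruth]:
    """Draw the homozygous progeny mosaics and the error-free framework map."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    L = config.chromosome_length
    lines = [f"L{i:03d}" for i in range(config.n_lines)]
    site_pos = {chrom: np.sort(parents.sites.loc[parents.sites["chrom"] == chrom,
                                                 "pos"].to_numpy())
                for chrom in config.chromosome_names}
    phase0, breakpoints = {}, {}
    for line in lines:
        for chrom in config.chromosome_names:
            phase0[(line, chrom)] = "A" if rng.random() < 0.5 else "B"
            k = rng.poisson(config.effective_crossovers)
            bps = []
            for _ in range(k):
                for _attempt in range(200):
                    b = int(rng.integers(1, L))
                    if np.min(np.abs(site_pos[chrom] - b)) > TAG_LENGTH + 4:
                        bps.append(b)
                        break
            breakpoints[(line, chrom)] = np.sort(np.array(bps, dtype=int))

    pop = Population(config, parents, lines, phase0, breakpoints,
                     framework=None)  # type: ignore[arg-type]
    n_mark = config.framework_markers_per_chromosome
    cm_per_bp = config.effective_crossovers * 100.0 / L
    meta, calls = [], []
    ids = []
    for chrom in config.chromosome_names:
        for j in range(n_mark):
            bp = int((j + 1) * L / (n_mark + 1))
            ids.append(f"S_{chrom}_{j:03d}")
            meta.append({"chrom": chrom, "cm": bp * cm_per_bp, "bp": bp})
            row = []
            for line in lines:
                call = pop.parent_at(line, chrom, bp)
                if config.marker_error_rate > 0 and rng.random() < config.marker_error_rate:
                    call = "B" if call == "A" else "A"
                row.append(call)
            calls.append(row)
    framework = FrameworkMap(pd.DataFrame(meta, index=ids),
                             pd.DataFrame(calls, index=ids, columns=lines))
    pop = dataclasses.replace(pop, framework=framework)
    truth = build_truth(parents, pop, enzyme)
    return pop, truth


@dataclass(frozen=True)
class ReadLabel:
    kind: str          # genomic | dimer
    sample: str
    tag: str | None    # truth tag for genomic reads


@dataclass
class SimReads:
    reads: list[RawRead]
    labels: list[ReadLabel]
    key: dict[str, str]  # sample -> barcode

    def __len__(self) -> int:
        return len(self.reads)

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for read in self.reads:
                qual = "".join(chr(q + 33) for q in read.qualities)
                fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")

    def write_qseq(self, path) -> None:
        with open(path, "w") as fh:
            for i, read in enumerate(self.reads):
                qual = "".join(chr(q + 64) for q in read.qualities)
                pf = "1" if read.passed_filter else "0"
                fh.write("\t".join(["SIM", "1", "1", "1", str(i), "0", "0", "1",
                                    read.sequence, qual, pf]) + "\n")

    def write_key(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tbarcode_sequence\tlane\n")
            for sample, bc in self.key.items():
                fh.write(f"{sample}\t{bc}\t1\n")


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    k = rng.binomial(len(seq), error_rate)
    if k == 0:
        return seq
    arr = np.array(list(seq))
    for pos in rng.choice(len(seq), size=k, replace=False):
        alts = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = alts[rng.integers(0, 3)]
    return "".join(arr)


def simulate_reads(population: Population, truth: SimTruth,
                   key: Mapping[str, str], config: SimConfig,
                   rng: np.random.Generator | None = None) -> SimReads:
    """Synthesize the 86 bp single-end reads of one multiplexed lane."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    missing = set(population.lines) - set(key)
    if missing:
        raise SimConfigError(f"no barcode assigned to lines: {sorted(missing)}")
    reads: list[RawRead] = []
    labels: list[ReadLabel] = []

    def finish(content: str, sample: str, kind: str, tag: str | None) -> None:
        seq = _mutate(content[:READ_LENGTH], rng, config.sequencing_error_rate)
        quals = (config.base_quality
                 + rng.integers(-2, 3, size=READ_LENGTH)).tolist()
        low_q = rng.random() < config.low_quality_read_fraction
        if low_q:
            quals[int(rng.integers(0, 72))] = int(rng.integers(2, 10))
        reads.append(RawRead(seq, quals, id=f"sim:{len(reads):07d}",
                             lane="1", passed_filter=not low_q))
        labels.append(ReadLabel(kind, sample, tag))

    presence = truth.presence
    for line in population.lines:
        barcode = key[line]
        present_tags = presence.index[presence[line].to_numpy()]
        depths = rng.poisson(config.mean_depth, size=len(present_tags))
        for tag, depth in zip(present_tags, depths):
            template = barcode + truth.templates[tag]
            for _ in range(int(depth)):
                finish(template, line, "genomic", tag)

    n_genomic = len(reads)
    f = config.dimer_read_fraction
    n_dimer = rng.poisson(n_genomic * f / (1 - f)) if f > 0 else 0
    line_list = list(population.lines)
    for _ in range(n_dimer):
        line = line_list[int(rng.integers(0, len(line_list)))]
        w = "A" if rng.random() < 0.5 else "T"
        core = key[line] + "C" + w + "G" + _ADAPTER_CONT
        filler = "".join(_BASES[rng.integers(0, 4, size=READ_LENGTH)])
        finish(core + filler, line, "dimer", None)

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    labels = [labels[i] for i in order]
    for i, read in enumerate(reads):
        read.id = f"sim:{i:07d}"
    return SimReads(reads, labels, dict(key))


@dataclass
class SimBundle:
    config: SimConfig
    parents: Parents
    population: Population
    truth: SimTruth
    barcodes: BarcodeSet
    key: dict[str, str]
    reads: SimReads


def simulate(config: SimConfig,
             barcodes: BarcodeSet | None = None) -> SimBundle:
    """Run the whole generator: parents, population, framework map, reads."""
    parents = simulate_parents(config)
    population, truth = simulate_population(parents, config)
    if barcodes is None:
        barcodes = generate_barcode_set(config.n_lines,
                                        seed=(config.seed + 3) % 2**31)
    key = {line: bc for line, bc in zip(population.lines, barcodes)}
    reads = simulate_reads(population, truth, key, config)
    return SimBundle(config, parents, population, truth, barcodes, key, reads)


def write_parents_fasta(parents: Parents, path_a, path_b) -> None:
    for path, parent in ((path_a, "A"), (path_b, "B")):
        records = [SeqRecord(Seq(seq), id=chrom, description=f"parent_{parent}")
                   for chrom, seq in parents.genomes[parent].items()]
        SeqIO.write(records, str(path), "fasta")


def write_truth(truth: SimTruth, path) -> None:
    truth.tags.join(truth.presence.astype(int)).to_csv(path, sep="\t")
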