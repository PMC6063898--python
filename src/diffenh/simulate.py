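"""Synthetic two-condition epigenome scenarios with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
a genome with non-overlapping genes and intergenic enhancers, each
enhancer in a chromatin state per condition (active / primed / poised /
inactive), histone-mark coverage tracks whose enrichment follows those
states (H3K4me1 at any marked enhancer, H3K27ac only at active ones,
H3K4me3 at TSSs), RNA-seq counts whose fold changes are coupled to
enhancer activation through nearest-gene links, and bench-assay tables
(qPCR Ct, luciferase, per-nucleus IF, dose-response) generated from
the same formulas the calculators invert.

Counts are Poisson per ChIP bin and negative-binomial for RNA-seq;
per-(enhancer, mark, condition) lognormal factors add biological
noise.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assays import four_param_logistic
from .genome import CoverageTrack, GeneModel, GenomicInterval
from .linkage import nearest_gene

STATES = ("active", "primed", "poised", "inactive")
MARKS = ("H3K4me1", "H3K27ac", "H3K4me3")
CONDITIONS = ("A", "B")

# which enhancer states carry which mark
MARK_STATES = {
    "H3K4me1": {"active", "primed", "poised"},
    "H3K27ac": {"active"},
}


class SizingError(ValueError):
    """Raised when genes/enhancers cannot be packed into the genome."""


@dataclass
class ScenarioConfig:
    """Knobs of a synthetic scenario.

    The default is the desk-scale reference scenario: one 10 Mb
    chromosome binned at 50 bp, 200 genes, 1000 enhancers of which 100
    are activated in condition B with a mean per-mark log2 gain of 1.5
    and a 4-fold mean expression gain at their nearest genes.
    """

    genome_length: int = 10_000_000  # total bp across chromosomes
    n_chromosomes: int = 1
    bin_size: int = 50
    n_genes: int = 200
    n_enhancers: int = 1_000
    n_activated: int = 100
    mark_effect_log2fc: float = 1.5
    expr_log2fc: float = 2.0
    background_rate: float = 2.0  # reads per bin
    peak_enrichment: float = 8.0  # fold over background at footprints
    noise_sd: float = 0.25  # log2 units, per (enhancer, mark, condition)
    seed: int = 0
    # structural parameters
    enhancer_width: int = 2_000  # footprint centered on the placement point
    tss_footprint: int = 1_000  # H3K4me3 width centered on the TSS
    gene_length_min: int = 2_000
    gene_length_max: int = 10_000
    tss_clearance: int = 3_000  # min enhancer distance from any TSS
    enhancer_gap: int = 600  # min gap between enhancer footprints
    rnaseq_dispersion: float = 0.1
    libsize: float = 1_000_000.0

    def validate(self) -> "ScenarioConfig":
        if self.n_chromosomes < 1 or self.genome_length % self.n_chromosomes:
            raise ValueError("genome_length must divide evenly among chromosomes")
        chrom_len = self.genome_length // self.n_chromosomes
        if self.bin_size <= 0 or chrom_len % self.bin_size:
            raise ValueError("bin_size must divide the per-chromosome length")
        if not (0 <= self.n_activated <= self.n_enhancers):
            raise ValueError("n_activated must be <= n_enhancers")
        for name in ("background_rate", "peak_enrichment", "libsize"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.rnaseq_dispersion < 0:
            raise ValueError("noise_sd and rnaseq_dispersion must be >= 0")
        if self.gene_length_min > self.gene_length_max:
            raise ValueError("gene_length_min must be <= gene_length_max")
        return self

    @property
    def chrom_lengths(self) -> dict[str, int]:
        length = self.genome_length // self.n_chromosomes
        return {f"chr{i + 1}": length for i in range(self.n_chromosomes)}


@dataclass
class GroundTruth:
    """What the generator planted, for downstream scoring."""

    genes: list[GeneModel]
    enhancers: list[GenomicInterval]  # named footprints
    states: pd.DataFrame  # index enhancer id, columns A, B with state labels
    activated_set: set[str]
    gene_links: dict[str, str]  # activated enhancer id -> nearest gene id
    true_expr_fc: pd.Series  # per-gene planted fold change (B over A)
    chrom_lengths: dict[str, int]

    def enhancer_by_id(self, name: str) -> GenomicInterval:
        for iv in self.enhancers:
            if iv.name == name:
                return iv
        raise KeyError(name)


class _Occupancy:
    """Disjoint sorted interval sets per chromosome for overlap rejection.

    Added intervals are coalesced with any they touch, so membership
    stays disjoint and a conflict test is a single bisect.
    """

    def __init__(self) -> None:
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def add(self, chrom: str, start: int, end: int) -> None:
        ivs = self._by_chrom.setdefault(chrom, [])
        lo = bisect.bisect_left(ivs, (start, end))
        while lo > 0 and ivs[lo - 1][1] >= start:
            lo -= 1
            start = min(start, ivs[lo][0])
            end = max(end, ivs[lo][1])
        hi = lo
        while hi < len(ivs) and ivs[hi][0] <= end:
            end = max(end, ivs[hi][1])
            hi += 1
        ivs[lo:hi] = [(start, end)]

    def conflicts(self, chrom: str, start: int, end: int) -> bool:
        ivs = self._by_chrom.get(chrom, [])
        i = bisect.bisect_left(ivs, (end, end))
        return i > 0 and ivs[i - 1][1] > start


def _pick_chrom(rng: np.random.Generator, chrom_lengths: dict[str, int]) -> str:
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    return chroms[rng.choice(len(chroms), p=weights / weights.sum())]


def make_genome(config: ScenarioConfig) -> GroundTruth:
    """Place genes and enhancers, assign states, plant expression effects.

    Genes are non-overlapping bodies with random strand, placed
    uniformly with rejection; enhancers are fixed-width footprints in
    intergenic space, kept clear of TSSs (``tss_clearance``) and of
    each other (``enhancer_gap``) so neighbouring catalog entries do
    not merge into mixed-state intervals.  State composition: the
    ``n_activated`` enhancers go primed→active in condition B; the
    remainder are split between stably active, stably primed,
    deactivated (active→primed), poised, and inactive.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    chrom_lengths = config.chrom_lengths

    genes: list[GeneModel] = []
    gene_occ = _Occupancy()
    max_attempts = 300 * max(1, config.n_genes)
    attempts = 0
    while len(genes) < config.n_genes:
        if attempts > max_attempts:
            raise SizingError(
                f"could not place {config.n_genes} genes in {config.genome_length} bp"
            )
        attempts += 1
        chrom = _pick_chrom(rng, chrom_lengths)
        length = int(rng.integers(config.gene_length_min, config.gene_length_max + 1))
        limit = chrom_lengths[chrom] - length
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        # 500 bp buffer keeps gene bodies strictly separated
        if gene_occ.conflicts(chrom, start - 500, start + length + 500):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene_{len(genes):04d}"
        gene_occ.add(chrom, start, start + length)
        genes.append(GeneModel(gene_id, GenomicInterval(chrom, start, start + length, strand, gene_id)))

    # blocked space for enhancers: padded gene bodies and TSS clearance zones
    blocked = _Occupancy()
    for g in genes:
        blocked.add(g.chrom, g.interval.start - 500, g.interval.end + 500)
        blocked.add(g.chrom, g.tss - config.tss_clearance, g.tss + config.tss_clearance + 1)

    enhancers: list[GenomicInterval] = []
    enh_occ = _Occupancy()
    half = config.enhancer_width // 2
    max_attempts = 300 * max(1, config.n_enhancers)
    attempts = 0
    while len(enhancers) < config.n_enhancers:
        if attempts > max_attempts:
            raise SizingError(
                f"could not place {config.n_enhancers} enhancers in intergenic space"
            )
        attempts += 1
        chrom = _pick_chrom(rng, chrom_lengths)
        center = int(rng.integers(half, chrom_lengths[chrom] - half))
        start, end = center - half, center + half
        if blocked.conflicts(chrom, start, end):
            continue
        if enh_occ.conflicts(chrom, start - config.enhancer_gap, end + config.enhancer_gap):
            continue
        name = f"truth_{len(enhancers):05d}"
        enh_occ.add(chrom, start, end)
        enhancers.append(GenomicInterval(chrom, start, end, ".", name))

    # state assignment
    ids = [iv.name for iv in enhancers]
    order = rng.permutation(len(ids))
    activated_ids = [ids[i] for i in order[: config.n_activated]]
    rest = [ids[i] for i in order[config.n_activated :]]
    states = pd.DataFrame(index=pd.Index(ids, name="enhancer_id"), columns=["A", "B"], dtype=object)
    for name in activated_ids:
        states.loc[name] = ["primed", "active"]
    # remaining composition mirrors a landscape where most enhancers are
    # stable and a minority lose acetylation in condition B
    fractions = [("active", "active", 0.35), ("primed", "primed", 0.35),
                 ("active", "primed", 0.10), ("poised", "poised", 0.10),
                 ("inactive", "inactive", 0.10)]
    counts = [int(round(f * len(rest))) for *_, f in fractions]
    counts[-1] = len(rest) - sum(counts[:-1])
    pos = 0
    for (state_a, state_b, _), n in zip(fractions, counts):
        for name in rest[pos : pos + n]:
            states.loc[name] = [state_a, state_b]
        pos += n

    gene_links: dict[str, str] = {}
    if genes:
        for name in activated_ids:
            iv = next(e for e in enhancers if e.name == name)
            gene_id, _ = nearest_gene(iv, genes)
            gene_links[name] = gene_id
    fc = pd.Series(1.0, index=pd.Index([g.gene_id for g in genes], name="gene_id"))
    for gene_id in gene_links.values():
        fc.loc[gene_id] = 2.0 ** config.expr_log2fc
    fc.name = "true_expr_fc"

    return GroundTruth(
        genes=genes,
        enhancers=enhancers,
        states=states,
        activated_set=set(activated_ids),
        gene_links=gene_links,
        true_expr_fc=fc,
        chrom_lengths=chrom_lengths,
    )


def simulate_mark_tracks(
    truth: GroundTruth, config: ScenarioConfig
) -> dict[tuple[str, str], CoverageTrack]:
    """Per-(mark, condition) raw-count coverage tracks.

    Bin counts are Poisson with mean ``background_rate`` genome-wide,
    multiplied by ``peak_enrichment`` over footprints where the mark is
    present (state-dependent for the enhancer marks; TSS footprints for
    H3K4me3), by 2^mark_effect_log2fc at activated enhancers in
    condition B, and by a per-(enhancer, mark, condition) lognormal
    noise factor 2^N(0, noise_sd).
    """
    config.validate()
    bs = config.bin_size
    n_enh = len(truth.enhancers)
    noise_rng = np.random.default_rng([config.seed, 202])
    enh_noise = noise_rng.normal(0.0, config.noise_sd, size=(n_enh, 2, 2))
    tss_noise = noise_rng.normal(0.0, config.noise_sd, size=(len(truth.genes), 2))

    tracks: dict[tuple[str, str], CoverageTrack] = {}
    for mark_idx, mark in enumerate(MARKS):
        for cond_idx, cond in enumerate(CONDITIONS):
            lam = {
                chrom: np.full(length // bs, config.background_rate)
                for chrom, length in truth.chrom_lengths.items()
            }
            if mark in MARK_STATES:
                present_states = MARK_STATES[mark]
                for i, iv in enumerate(truth.enhancers):
                    state = truth.states.loc[iv.name, cond]
                    if state not in present_states:
                        continue
                    boost = 1.0
                    if cond == "B" and iv.name in truth.activated_set:
                        boost = 2.0 ** config.mark_effect_log2fc
                    factor = (
                        config.peak_enrichment
                        * boost
                        * 2.0 ** enh_noise[i, mark_idx, cond_idx]
                    )
                    b0, b1 = iv.start // bs, (iv.end - 1) // bs + 1
                    lam[iv.chrom][b0:b1] = config.background_rate * factor
            else:  # H3K4me3 marks TSSs of all genes, both conditions
                half = config.tss_footprint // 2
                for j, g in enumerate(truth.genes):
                    factor = config.peak_enrichment * 2.0 ** tss_noise[j, cond_idx]
                    arr = lam[g.chrom]
                    b0 = max(0, (g.tss - half) // bs)
                    b1 = min(len(arr), (g.tss + half - 1) // bs + 1)
                    arr[b0:b1] = config.background_rate * factor
            count_rng = np.random.default_rng(
                [config.seed, 303, mark_idx, cond_idx]
            )
            data = {chrom: count_rng.poisson(arr).astype(float) for chrom, arr in lam.items()}
            total = float(sum(a.sum() for a in data.values()))
            tracks[(mark, cond)] = CoverageTrack(bs, data, total, "raw")
    return tracks


def simulate_rnaseq(
    truth: GroundTruth,
    config: ScenarioConfig,
    libsize_a: float | None = None,
    libsize_b: float | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Overdispersed per-gene counts for the two conditions.

    Baseline relative expression is lognormal across genes; genes
    nearest an activated enhancer carry the planted fold change in
    condition B.  Counts are negative binomial with gene-level
    dispersion ``rnaseq_dispersion``; expected depth scales with the
    per-condition library size.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 404])
    la = config.libsize if libsize_a is None else float(libsize_a)
    lb = config.libsize if libsize_b is None else float(libsize_b)
    gene_ids = [g.gene_id for g in truth.genes]
    rel = np.exp(rng.normal(0.0, 1.0, size=len(gene_ids)))
    rel_sum = rel.sum()
    fc = truth.true_expr_fc.loc[gene_ids].to_numpy()
    mu_a = rel / rel_sum * la
    mu_b = rel * fc / rel_sum * lb

    def draw(mu: np.ndarray) -> np.ndarray:
        if config.rnaseq_dispersion == 0:
            return rng.poisson(mu).astype(int)
        n = 1.0 / config.rnaseq_dispersion
        p = n / (n + mu)
        return rng.negative_binomial(n, p)

    index = pd.Index(gene_ids, name="gene_id")
    counts_a = pd.Series(draw(mu_a), index=index, name="count")
    counts_b = pd.Series(draw(mu_b), index=index, name="count")
    return counts_a, counts_b


# ---------------------------------------------------------------------------
# assay tables
# ---------------------------------------------------------------------------

@dataclass
class AssayScenario:
    """Planted parameters for the bench-assay generators."""

    interaction_frequencies: dict[str, float] = field(
        default_factory=lambda: {"F1": 0.1, "F2": 0.2, "F3": 0.3, "F4": 1.0, "F5": 0.25, "F6": 0.1}
    )
    chip_efficiency: float = 0.02  # fraction of input recovered
    input_fraction: float = 0.01
    luciferase_activities: dict[str, float] = field(
        default_factory=lambda: {"R1": 2.0, "R7": 6.0, "R10": 1.5}
    )
    ddct_fold_change: float = 16.0
    ic50: float = 10.0  # µM
    hill: float = 2.0  # steep slope typical of cytotoxic viability curves
    response_bottom: float = 0.0
    response_top: float = 1.0
    positive_fraction: float = 0.24
    n_nuclei: int = 100
    ct_intercept: float = 20.0  # Ct of unit template
    ct_noise_sd: float = 0.0  # cycles
    reading_cv: float = 0.0  # luciferase reading noise
    response_cv: float = 0.05  # dose-response noise
    n_replicates: int = 3
    doses: tuple[float, ...] = ()  # default: 8 log-spaced around ic50
    seed: int = 0


def simulate_assays(scenario: AssayScenario) -> dict[str, pd.DataFrame]:
    """Generate assay tables from planted parameters.

    Ct values follow Ct = intercept − log2(template) + N(0, sd), so at
    zero noise every calculator inverts its table exactly.  Dose-
    response points come from the four-parameter logistic; per-nucleus
    signals from a two-component positive/negative mixture.
    """
    rng = np.random.default_rng([scenario.seed, 505])
    sd = scenario.ct_noise_sd
    rep = scenario.n_replicates

    def ct(template: float, n: int = rep) -> np.ndarray:
        return scenario.ct_intercept - np.log2(template) + rng.normal(0.0, sd, size=n)

    # --- 3C: one BAC control row plus one row per restriction fragment
    rows = [
        {"sample": "BAC", "role": "control_BAC", **{f"ct{r + 1}": v for r, v in enumerate(ct(1.0))}}
    ]
    for frag, freq in scenario.interaction_frequencies.items():
        rows.append(
            {"sample": frag, "role": "test_3C", **{f"ct{r + 1}": v for r, v in enumerate(ct(freq))}}
        )
    three_c = pd.DataFrame(rows)

    # --- ChIP-qPCR: input is input_fraction of chromatin, pulldown recovers
    # chip_efficiency of it
    total_template = 1.0
    chip_rows = [
        {
            "sample": "input",
            "role": "input",
            **{f"ct{r + 1}": v for r, v in enumerate(ct(scenario.input_fraction * total_template))},
        },
        {
            "sample": "chip",
            "role": "chip",
            **{f"ct{r + 1}": v for r, v in enumerate(ct(scenario.chip_efficiency * total_template))},
        },
    ]
    chip = pd.DataFrame(chip_rows)

    # --- dual luciferase
    lrows = []
    base_ratio = 0.5  # firefly/renilla of the empty vector
    for construct in ["vector", *scenario.luciferase_activities]:
        activity = 1.0 if construct == "vector" else scenario.luciferase_activities[construct]
        renilla = 1e5 * float(rng.lognormal(0.0, 0.1))
        firefly = activity * base_ratio * renilla
        if scenario.reading_cv > 0:
            firefly *= 1.0 + rng.normal(0.0, scenario.reading_cv)
            renilla *= 1.0 + rng.normal(0.0, scenario.reading_cv)
        lrows.append({"construct": construct, "firefly": firefly, "renilla": renilla})
    luciferase = pd.DataFrame(lrows)

    # --- RT-qPCR for delta-delta-Ct
    ref_template = 1.0
    rt_rows = []
    for sample, gene_template in (
        ("control", 1.0),
        ("test", scenario.ddct_fold_change),
    ):
        rt_rows.append(
            {"sample": sample, "target": "gene", **{f"ct{r + 1}": v for r, v in enumerate(ct(gene_template))}}
        )
        rt_rows.append(
            {"sample": sample, "target": "reference", **{f"ct{r + 1}": v for r, v in enumerate(ct(ref_template))}}
        )
    rt = pd.DataFrame(rt_rows)

    # --- dose-response
    doses = (
        np.asarray(scenario.doses, dtype=float)
        if scenario.doses
        else scenario.ic50 * np.logspace(-2, 2, 8)
    )
    dr_rows = []
    for dose in doses:
        ideal = four_param_logistic(
            np.array([dose]),
            scenario.response_bottom,
            scenario.response_top,
            scenario.hill,
            np.log(scenario.ic50),
        )[0]
        for r in range(rep):
            noise = 1.0 + rng.normal(0.0, scenario.response_cv) if scenario.response_cv > 0 else 1.0
            dr_rows.append({"dose": dose, "replicate": r + 1, "response": ideal * noise})
    dose_response = pd.DataFrame(dr_rows)

    # --- per-nucleus immunofluorescence (target channel + negative control)
    n = scenario.n_nuclei
    positive = rng.random(n) < scenario.positive_fraction
    area = rng.normal(100.0, 10.0, size=n).clip(min=20.0)
    neg_intensity = rng.lognormal(0.0, 0.2, size=n)
    pos_intensity = 10.0 * rng.lognormal(0.0, 0.2, size=n)
    target_intensity = np.where(positive, pos_intensity, neg_intensity)
    control_intensity = rng.lognormal(0.0, 0.2, size=n)
    nrows = []
    for i in range(n):
        nrows.append(
            {"nucleus_id": f"nuc_{i:03d}", "channel": "MGMT", "area": area[i], "mean_intensity": target_intensity[i]}
        )
        nrows.append(
            {"nucleus_id": f"nuc_{i:03d}", "channel": "control", "area": area[i], "mean_intensity": control_intensity[i]}
        )
    nuclei = pd.DataFrame(nrows)
    nuclei.attrs["true_positive"] = positive

    return {
        "three_c": three_c,
        "chip": chip,
        "luciferase": luciferase,
        "rt_qpcr": rt,
        "dose_response": dose_response,
        "nuclei": nuclei,
    }


# ---------------------------------------------------------------------------
# scoring and serialization
# ---------------------------------------------------------------------------

def score_recovery(
    predicted: "list[GenomicInterval] | set[str]",
    truth: GroundTruth,
    catalog_intervals: list[GenomicInterval] | None = None,
) -> tuple[float, float]:
    """Precision and recall of a predicted activated-enhancer set.

    ``predicted`` is either intervals, or catalog ids together with the
    catalog's intervals.  A prediction is a true positive when it
    overlaps a planted activated footprint; recall is the fraction of
    activated footprints covered by some prediction.
    """
    if isinstance(predicted, set):
        if catalog_intervals is None:
            raise ValueError("catalog_intervals required when predicted is an id set")
        intervals = [iv for iv in catalog_intervals if iv.name in predicted]
    else:
        intervals = list(predicted)
    activated = [truth.enhancer_by_id(name) for name in truth.activated_set]
    if not intervals:
        return (float("nan"), 0.0 if activated else float("nan"))
    tp_pred = sum(1 for iv in intervals if any(iv.overlaps(a) for a in activated))
    covered = sum(1 for a in activated if any(a.overlaps(iv) for iv in intervals))
    precision = tp_pred / len(intervals)
    recall = covered / len(activated) if activated else float("nan")
    return precision, recall


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "chrom_lengths": truth.chrom_lengths,
        "activated_set": sorted(truth.activated_set),
        "gene_links": truth.gene_links,
        "true_expr_fc": truth.true_expr_fc.to_dict(),
        "states": {name: list(row) for name, row in truth.states.iterrows()},
        "enhancers": [
            [iv.chrom, iv.start, iv.end, iv.name] for iv in truth.enhancers
        ],
        "genes": [
            [g.gene_id, g.chrom, g.interval.start, g.interval.end, g.strand]
            for g in truth.genes
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    genes = [
        GeneModel(gid, GenomicInterval(chrom, start, end, strand, gid))
        for gid, chrom, start, end, strand in payload["genes"]
    ]
    enhancers = [
        GenomicInterval(chrom, start, end, ".", name)
        for chrom, start, end, name in payload["enhancers"]
    ]
    states = pd.DataFrame.from_dict(payload["states"], orient="index", columns=["A", "B"])
    states.index.name = "enhancer_id"
    states = states.loc[[iv.name for iv in enhancers]]
    fc = pd.Series(payload["true_expr_fc"], name="true_expr_fc")
    fc.index.name = "gene_id"
    return GroundTruth(
        genes=genes,
        enhancers=enhancers,
        states=states,
        activated_set=set(payload["activated_set"]),
        gene_links=payload["gene_links"],
        true_expr_fc=fc.loc[[g.gene_id for g in genes]],
        chrom_lengths={k: int(v) for k, v in payload["chrom_lengths"].items()},
    )
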