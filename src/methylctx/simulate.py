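"""Synthetic methylome generator.

Emulates the chromatin and pathway structure the analysis assumes: each
chromosome carries a pericentric heterochromatin domain flanked by
euchromatic arms; per-domain, per-subcontext site-level models are
two-component beta mixtures over per-site methylation probability (bimodal
where maintenance methylation is efficient); transposon bodies carry their
family's signature (chromomethyltransferase-like subcontext bias, or
RdDM-like uniform methylation) while transposon edges and gene flanks carry
a context-independent exponential component emulating small-RNA-directed
methylation; an unmethylated control contig mimics the chloroplast; reads
are summarised directly as per-cytosine counts with Poisson coverage and a
conversion-failure rate (unmethylated calls read as methylated with
probability epsilon).

Genotype presets multiply domain means (e.g. a cmt2-like genotype reduces
favored CHH subcontexts to 20% and the rest to 80% genome-wide; an
nrpe1-like genotype flattens euchromatic CHH and silences the edge
component). The same seed and configuration always produce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .context import CHH_SUBCONTEXTS, CONTEXT_CLASS, SUBCONTEXTS, cytosine_table
from .io import FeatureRecord, GenomeSequence, SrnaLocusTable
from .methylome import RegionSpec

CONTROL_DOMAIN = "control"


# ---------------------------------------------------------------------------
# site-level model


@dataclass(frozen=True)
class BetaMixture:
    """pi_high * Beta(a_high, b_high) + (1 - pi_high) * Beta(a_low, b_low)."""

    pi_high: float
    a_high: float
    b_high: float
    a_low: float
    b_low: float

    @property
    def mean(self) -> float:
        m1 = self.a_high / (self.a_high + self.b_high)
        m0 = self.a_low / (self.a_low + self.b_low)
        return self.pi_high * m1 + (1 - self.pi_high) * m0

    @staticmethod
    def from_mean(
        target: float,
        high: tuple[float, float],
        low: tuple[float, float],
    ) -> "BetaMixture":
        """Mixture with the given components and mixing weight solved so the
        overall mean equals ``target``."""
        m1 = high[0] / sum(high)
        m0 = low[0] / sum(low)
        if not min(m0, m1) <= target <= max(m0, m1):
            raise ValueError(f"target mean {target} outside component means")
        pi = (target - m0) / (m1 - m0)
        return BetaMixture(pi, *high, *low)

    @staticmethod
    def unimodal(a: float, b: float) -> "BetaMixture":
        return BetaMixture(0.0, 1.0, 1.0, a, b)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        high = rng.random(n) < self.pi_high
        out = rng.beta(self.a_low, self.b_low, n)
        k = int(high.sum())
        if k:
            out[high] = rng.beta(self.a_high, self.b_high, k)
        return out


SiteModels = dict[str, BetaMixture]  # subcontext -> mixture


def uniform_models(mean_by_key: dict[str, float], concentration: float = 7.0
                   ) -> SiteModels:
    """Unimodal Beta models with the given means and common concentration."""
    out = {}
    for key, m in mean_by_key.items():
        out[key] = BetaMixture.unimodal(m * concentration,
                                        (1 - m) * concentration)
    return out


# ---------------------------------------------------------------------------
# plans


@dataclass(frozen=True)
class ContigPlan:
    name: str
    length: int
    gc: float = 0.36
    is_control: bool = False
    het_span: tuple[int, int] | None = None  # pericentric heterochromatin


@dataclass(frozen=True)
class TransposonFamilyPlan:
    family: str
    n: int
    length_range: tuple[int, int]
    domain: str  # "heterochromatin" or "euchromatin"
    signature: str  # "CMT-like", "RdDM-like" or "mixed"
    edge_amplitude: float = 0.0
    edge_decay_bp: float = 300.0
    body_models: SiteModels | None = None  # None -> inherit domain models


@dataclass(frozen=True)
class GenePlan:
    n: int
    length_range: tuple[int, int]
    island_amplitude: float = 0.0  # CHH-island component in gene flanks
    island_decay_bp: float = 300.0


@dataclass(frozen=True)
class GenotypeEffect:
    """Multipliers on mean site-level, keyed by (domain, subcontext/class).

    Lookup precedence for a site with domain d, subcontext k, class c:
    (d,k), (d,c), (d,"*"), ("*",k), ("*",c), ("*","*"); default 1.
    ``edge_multiplier`` scales transposon-edge amplitudes,
    ``island_multiplier`` gene-flank CHH islands.
    """

    level_multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    edge_multiplier: float = 1.0
    island_multiplier: float = 1.0

    def multiplier(self, domain: str, subcontext: str) -> float:
        cls = CONTEXT_CLASS[subcontext]
        for key in ((domain, subcontext), (domain, cls), (domain, "*"),
                    ("*", subcontext), ("*", cls), ("*", "*")):
            if key in self.level_multipliers:
                return self.level_multipliers[key]
        return 1.0


@dataclass(frozen=True)
class SrnaPlan:
    n_small_loci: int = 300  # 20-22 nt, undisturbed (anchor normalization)
    n_large_loci: int = 1000  # 23-24 nt
    log_mean: float = np.log(80.0)
    log_sd: float = 1.0
    min_mu: float = 10.0
    dispersion: float = 0.2
    fraction_down: float = 0.72
    fold_change: float = 8.0
    fraction_up: float = 0.0
    fold_up: float = 4.0
    n_wt: int = 2
    n_mut: int = 2
    sample_scales: tuple[float, ...] = (1.0, 1.3, 0.8, 1.1)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    contigs: tuple[ContigPlan, ...]
    site_models: dict[str, SiteModels]  # domain -> subcontext -> mixture
    coverage_lambda: float = 10.0
    conversion_failure: float = 0.005
    transposons: tuple[TransposonFamilyPlan, ...] = ()
    genes: GenePlan | None = None
    genotypes: dict[str, GenotypeEffect] = field(default_factory=dict)
    srna: SrnaPlan = SrnaPlan()
    core_margin_bp: int = 2000  # feature neighborhood excluded from "core" regions


def _child_rng(seed: int, *labels: str) -> np.random.Generator:
    digest = hashlib.sha256("/".join(labels).encode()).digest()
    tag = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


# ---------------------------------------------------------------------------
# genome + features


def _subtract_margins(
    intervals: list[tuple[str, int, int]],
    features: list[FeatureRecord],
    margin: int,
) -> list[tuple[str, int, int]]:
    out = []
    for contig, start, end in intervals:
        cuts = sorted(
            (max(f.start - margin, start), min(f.end + margin, end))
            for f in features
            if f.contig == contig and f.start - margin < end
            and f.end + margin > start
        )
        cursor = start
        for s, e in cuts:
            if s > cursor:
                out.append((contig, cursor, s))
            cursor = max(cursor, e)
        if cursor < end:
            out.append((contig, cursor, end))
    return out


def _place_features(
    rng: np.random.Generator,
    intervals: list[tuple[str, int, int]],
    lengths: np.ndarray,
    occupied: dict[str, list[tuple[int, int]]],
) -> list[tuple[str, int, int]]:
    """Place features of given lengths into intervals without overlap."""
    weights = np.array([e - s for _, s, e in intervals], dtype=float)
    assignment = rng.choice(len(intervals), size=lengths.size,
                            p=weights / weights.sum())
    placements = []
    for idx, (contig, start, end) in enumerate(intervals):
        lens = lengths[assignment == idx]
        if lens.size == 0:
            continue
        slack = (end - start) - int(lens.sum())
        if slack < 0:
            raise ValueError(
                f"features do not fit in [{start},{end}) of {contig}"
            )
        cuts = np.sort(rng.uniform(0, slack, lens.size))
        offsets = cuts + np.concatenate([[0], np.cumsum(lens[:-1])])
        for off, ln in zip(offsets, lens):
            s = start + int(off)
            placements.append((contig, s, s + int(ln)))
            occupied.setdefault(contig, []).append((s, s + int(ln)))
    return placements


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[FeatureRecord], RegionSpec]:
    """Random genome, feature annotation and domain regions.

    Nucleotides are i.i.d. at the configured GC content. Transposons are
    placed without overlap inside their domain; genes inside euchromatin.
    Region names: heterochromatin, euchromatin (per domain plan) and
    *_core variants excluding ``core_margin_bp`` neighborhoods of feature
    boundaries (where edge/island components make domain means impure).
    """
    rng = _child_rng(config.seed, "genome")
    contigs: dict[str, str] = {}
    het: list[tuple[str, int, int]] = []
    eu: list[tuple[str, int, int]] = []
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    for plan in config.contigs:
        p_gc = plan.gc / 2
        p_at = (1 - plan.gc) / 2
        codes = rng.choice(4, size=plan.length, p=[p_at, p_gc, p_gc, p_at])
        contigs[plan.name] = lut[codes].tobytes().decode("ascii")
        if plan.is_control:
            continue
        if plan.het_span is not None:
            s, e = plan.het_span
            het.append((plan.name, s, e))
            if s > 0:
                eu.append((plan.name, 0, s))
            if e < plan.length:
                eu.append((plan.name, e, plan.length))
        else:
            eu.append((plan.name, 0, plan.length))

    genome = GenomeSequence(contigs)

    features: list[FeatureRecord] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    place_rng = _child_rng(config.seed, "features")
    for plan in config.transposons:
        intervals = het if plan.domain == "heterochromatin" else eu
        if not intervals:
            raise ValueError(f"no {plan.domain} intervals to place {plan.family}")
        lengths = place_rng.integers(plan.length_range[0],
                                     plan.length_range[1] + 1, plan.n)
        for contig, s, e in _place_features(place_rng, intervals, lengths,
                                            occupied):
            strand = "+" if place_rng.random() < 0.5 else "-"
            features.append(FeatureRecord(contig, s, e, strand, "transposon",
                                          plan.family))
    if config.genes is not None:
        lengths = place_rng.integers(config.genes.length_range[0],
                                     config.genes.length_range[1] + 1,
                                     config.genes.n)
        # avoid stacking genes onto transposons: subtract occupied arms space
        free_eu = _subtract_margins(
            eu, [f for f in features if f.feature_type == "transposon"], 100
        )
        for contig, s, e in _place_features(place_rng, free_eu, lengths,
                                            occupied):
            strand = "+" if place_rng.random() < 0.5 else "-"
            features.append(FeatureRecord(contig, s, e, strand, "gene", None))
    features.sort(key=lambda f: (f.contig, f.start))

    regions = {
        "heterochromatin": het,
        "euchromatin": eu,
        "heterochromatin_core": _subtract_margins(het, features,
                                                  config.core_margin_bp),
        "euchromatin_core": _subtract_margins(eu, features,
                                              config.core_margin_bp),
    }
    return genome, features, RegionSpec({k: v for k, v in regions.items() if v})


# ---------------------------------------------------------------------------
# methylome


def _domain_labels(config: SimulationConfig, sites: pd.DataFrame) -> np.ndarray:
    labels = np.full(len(sites), "euchromatin", dtype=object)
    contig_arr = sites["contig"].to_numpy()
    pos0 = sites["pos"].to_numpy() - 1
    for plan in config.contigs:
        mask = contig_arr == plan.name
        if plan.is_control:
            labels[mask] = CONTROL_DOMAIN
        elif plan.het_span is not None:
            s, e = plan.het_span
            labels[mask & (pos0 >= s) & (pos0 < e)] = "heterochromatin"
    return labels


def simulate_methylome(
    genome: GenomeSequence,
    features: list[FeatureRecord],
    config: SimulationConfig,
    genotype: str = "wt",
) -> pd.DataFrame:
    """Per-cytosine methylation calls (CX-report layout) for one genotype.

    For each classifiable cytosine: the per-site methylation probability is
    drawn from its domain's (or overlapping transposon family's) subcontext
    mixture, scaled by the genotype multiplier; context-independent edge and
    CHH-island components decay exponentially from feature boundaries;
    coverage is Poisson; methylated calls are binomial with success
    probability p + (1-p) * epsilon. The control contig is fully
    unmethylated (p = 0).
    """
    if genotype not in config.genotypes:
        raise ValueError(f"unknown genotype {genotype!r}")
    effect = config.genotypes[genotype]
    rng = _child_rng(config.seed, "methylome", genotype)

    sites = cytosine_table(genome)
    n = len(sites)
    domain = _domain_labels(config, sites)
    sub_arr = sites["subcontext"].to_numpy()
    pos0 = sites["pos"].to_numpy() - 1
    contig_arr = sites["contig"].to_numpy()

    p = np.zeros(n)
    for dom in np.unique(domain):
        if dom == CONTROL_DOMAIN:
            continue
        models = config.site_models[dom]
        dmask = domain == dom
        for key in SUBCONTEXTS:
            idx = np.flatnonzero(dmask & (sub_arr == key))
            if idx.size:
                p[idx] = models[key].sample(rng, idx.size)

    # transposon bodies: family signature models override the domain draw
    plans = {t.family: t for t in config.transposons}
    for family, plan in plans.items():
        if plan.body_models is None:
            continue
        body = np.zeros(n, dtype=bool)
        for f in features:
            if f.family != family:
                continue
            body |= (contig_arr == f.contig) & (pos0 >= f.start) & (pos0 < f.end)
        for key in SUBCONTEXTS:
            idx = np.flatnonzero(body & (sub_arr == key))
            if idx.size:
                p[idx] = plan.body_models[key].sample(rng, idx.size)

    # genotype multipliers on the drawn per-site probabilities
    mult = np.ones(n)
    for dom in np.unique(domain):
        if dom == CONTROL_DOMAIN:
            continue
        dmask = domain == dom
        for key in SUBCONTEXTS:
            m = effect.multiplier(dom, key)
            if m != 1.0:
                mult[dmask & (sub_arr == key)] = m
    p *= mult

    # context-independent transposon-edge component
    window = {f: 4 * plans[f].edge_decay_bp for f in plans}
    for f in features:
        if f.feature_type != "transposon":
            continue
        plan = plans[f.family]
        amp = plan.edge_amplitude * effect.edge_multiplier
        if amp <= 0:
            continue
        w = window[f.family]
        near = (
            (contig_arr == f.contig)
            & (pos0 >= f.start - w) & (pos0 < f.end + w)
        )
        idx = np.flatnonzero(near)
        d = np.minimum(np.abs(pos0[idx] - f.start),
                       np.abs(pos0[idx] - (f.end - 1)))
        p[idx] = p[idx] + amp * np.exp(-d / plan.edge_decay_bp)

    # gene-flanking CHH islands (outside the body only)
    if config.genes is not None and config.genes.island_amplitude > 0:
        amp = config.genes.island_amplitude * effect.island_multiplier
        decay = config.genes.island_decay_bp
        w = 4 * decay
        is_chh = np.isin(sub_arr, CHH_SUBCONTEXTS)
        for f in features:
            if f.feature_type != "gene":
                continue
            flank = (
                (contig_arr == f.contig) & is_chh
                & (((pos0 >= f.start - w) & (pos0 < f.start))
                   | ((pos0 >= f.end) & (pos0 < f.end + w)))
            )
            idx = np.flatnonzero(flank)
            d = np.minimum(np.abs(pos0[idx] - f.start),
                           np.abs(pos0[idx] - (f.end - 1)))
            p[idx] = p[idx] + amp * np.exp(-d / decay)

    p = np.clip(p, 0.0, 1.0)
    p[domain == CONTROL_DOMAIN] = 0.0

    cov = rng.poisson(config.coverage_lambda, n)
    p_obs = p + (1 - p) * config.conversion_failure
    n_meth = rng.binomial(cov, p_obs)

    out = sites[["contig", "pos", "strand", "subcontext", "context"]].copy()
    out["n_meth"] = n_meth
    out["n_unmeth"] = cov - n_meth
    out["true_p"] = p
    out["domain"] = domain
    return out[["contig", "pos", "strand", "n_meth", "n_unmeth", "context",
                "subcontext", "true_p", "domain"]]


# ---------------------------------------------------------------------------
# small-RNA counts


def simulate_srna_counts(
    config: SimulationConfig, mutant_label: str = "mutant"
) -> SrnaLocusTable:
    """NB locus-count table with a configured down-regulated fraction.

    20-22-nt loci are undisturbed across conditions (they anchor the
    median-of-ratios normalization); the configured fraction of 23-24-nt
    loci is scaled down by the fold change in mutant samples. Per-sample
    library-scale factors emulate unequal sequencing depth.
    """
    plan = config.srna
    rng = _child_rng(config.seed, "srna", mutant_label)
    n_samples = plan.n_wt + plan.n_mut
    scales = np.asarray(plan.sample_scales[:n_samples], dtype=float)
    if scales.size != n_samples:
        raise ValueError("sample_scales shorter than the number of samples")
    samples = [f"wt_{i+1}" for i in range(plan.n_wt)] + [
        f"{mutant_label}_{i+1}" for i in range(plan.n_mut)
    ]
    conditions = {s: ("wt" if s.startswith("wt_") else "mutant") for s in samples}
    is_mut = np.array([conditions[s] == "mutant" for s in samples])

    def _loci(n, size_class, start_id):
        mu = np.maximum(
            rng.lognormal(plan.log_mean, plan.log_sd, n), plan.min_mu
        )
        ids = [f"locus_{start_id + i:05d}" for i in range(n)]
        pos = rng.integers(0, 1_000_000, n)
        loci = pd.DataFrame(
            {"locus_id": ids, "contig": "chr1", "start": pos,
             "end": pos + rng.integers(100, 1000, n), "size_class": size_class}
        )
        return loci, mu

    small_loci, small_mu = _loci(plan.n_small_loci, "20-22", 0)
    large_loci, large_mu = _loci(plan.n_large_loci, "23-24",
                                 plan.n_small_loci)

    n_down = int(round(plan.fraction_down * plan.n_large_loci))
    n_up = int(round(plan.fraction_up * plan.n_large_loci))
    perm = rng.permutation(plan.n_large_loci)
    down_idx, up_idx = perm[:n_down], perm[n_down:n_down + n_up]
    fold = np.ones(plan.n_large_loci)
    fold[down_idx] = 1.0 / plan.fold_change
    fold[up_idx] = plan.fold_up

    def _counts(mu, fold_vec):
        # mean matrix: locus x sample
        mean = mu[:, None] * scales[None, :]
        if fold_vec is not None:
            mean = mean * np.where(is_mut[None, :], fold_vec[:, None], 1.0)
        r = 1.0 / plan.dispersion
        return rng.negative_binomial(r, r / (r + mean))

    counts = np.vstack([_counts(small_mu, None), _counts(large_mu, fold)])
    loci = pd.concat([small_loci, large_loci], ignore_index=True)
    counts_df = pd.DataFrame(counts, index=loci["locus_id"], columns=samples)
    table = SrnaLocusTable(loci, counts_df, conditions)
    table.true_down = set(large_loci["locus_id"].iloc[down_idx])  # type: ignore[attr-defined]
    table.true_up = set(large_loci["locus_id"].iloc[up_idx])  # type: ignore[attr-defined]
    return table


# read-length profile emulation: peaks at 21 nt (miRNA) and 24 nt (siRNA)
_LENGTHS = np.arange(18, 31)
_BASE_LENGTH_WEIGHTS = np.array(
    [0.5, 0.8, 1.5, 6.0, 2.5, 2.0, 12.0, 1.5, 0.8, 0.5, 0.4, 0.3, 0.2]
)


def simulate_size_counts(
    config: SimulationConfig,
    genotype_24nt_multipliers: dict[str, float],
    n_reads: int = 1_000_000,
) -> pd.DataFrame:
    """Read-length count table (length x sample).

    ``genotype_24nt_multipliers`` maps sample name -> multiplier on the
    23-24-nt mass (e.g. 0.1 for an nrpd1-like sample that has lost 90% of
    its 24-nt small RNAs); other lengths keep their absolute weight, so
    fractions redistribute as they would in a resequenced library.
    """
    rng = _child_rng(config.seed, "size_profile")
    data = {}
    for sample, mult in genotype_24nt_multipliers.items():
        w = _BASE_LENGTH_WEIGHTS.copy()
        w[(_LENGTHS == 23) | (_LENGTHS == 24)] *= mult
        probs = w / w.sum()
        data[sample] = rng.multinomial(n_reads, probs)
    return pd.DataFrame(data, index=_LENGTHS)


def expected_size_fraction(multiplier: float, length: int = 24) -> float:
    """Generative expectation of one length's fraction under a 23-24-nt
    multiplier (for parameter-recovery checks)."""
    w = _BASE_LENGTH_WEIGHTS.copy()
    w[(_LENGTHS == 23) | (_LENGTHS == 24)] *= multiplier
    return float(w[_LENGTHS == length][0] / w.sum())


# ---------------------------------------------------------------------------
# presets


def _arabidopsis_site_models() -> dict[str, SiteModels]:
    het: SiteModels = {}
    eu: SiteModels = {}

    # CG: efficiently maintained, strongly bimodal
    for key in ("CGA", "CGT", "CGC", "CGG"):
        het[key] = BetaMixture.from_mean(0.85, high=(19, 1), low=(0.2, 20))
        eu[key] = BetaMixture.from_mean(0.25, high=(19, 1), low=(0.2, 20))

    # CHG heterochromatin: CAG/CTG bimodal at 0.40; CCG unimodal
    # low-to-intermediate at half that level
    for key in ("CAG", "CTG"):
        het[key] = BetaMixture.from_mean(0.40, high=(8, 1.5), low=(0.5, 10))
        eu[key] = BetaMixture.from_mean(0.08, high=(8, 1.5), low=(0.5, 10))
    het["CCG"] = BetaMixture.unimodal(3, 12)  # mean 0.20
    eu["CCG"] = BetaMixture.from_mean(0.08, high=(8, 1.5), low=(0.5, 10))

    # CHH heterochromatin: favored CAA/CTA 0.375; CCC/CCT lowest 0.05;
    # remaining subcontexts 0.10. Arms: uniform 0.02 in all nine.
    for key in CHH_SUBCONTEXTS:
        eu[key] = BetaMixture.unimodal(0.3, 14.7)  # mean 0.02
    for key in ("CAA", "CTA"):
        het[key] = BetaMixture.from_mean(0.375, high=(5, 3), low=(0.3, 6))
    for key in ("CCC", "CCT"):
        het[key] = BetaMixture.unimodal(0.5, 9.5)  # mean 0.05
    for key in ("CAT", "CAC", "CTT", "CTC", "CCA"):
        het[key] = BetaMixture.unimodal(0.7, 6.3)  # mean 0.10
    return {"heterochromatin": het, "euchromatin": eu}


def _rddm_body_models(eu: SiteModels) -> SiteModels:
    """RdDM-like transposon body: uniform moderate CHH, no subcontext bias."""
    out = dict(eu)
    for key in CHH_SUBCONTEXTS:
        out[key] = BetaMixture.unimodal(0.1 * 7, 0.9 * 7)  # mean 0.10
    for key in ("CAG", "CTG", "CCG"):
        out[key] = BetaMixture.from_mean(0.12, high=(8, 1.5), low=(0.5, 10))
    return out


def arabidopsis_like(
    seed: int,
    chrom_length: int = 2_000_000,
    control_length: int = 120_000,
    coverage_lambda: float = 10.0,
    conversion_failure: float = 0.005,
    srna: SrnaPlan | None = None,
) -> SimulationConfig:
    """Desk-scale A. thaliana-like preset.

    One 2-Mb chromosome whose central 20% is pericentric heterochromatin,
    plus an unmethylated 120-kb control contig standing in for the
    chloroplast. Heterochromatic means: CAA/CTA 0.375, CCC/CCT 0.05, other
    CHH 0.10, CAG/CTG 0.40 (bimodal), CCG 0.20 (unimodal), CG 0.85.
    Euchromatic arms: CHH 0.02, CHG 0.08, CG 0.25. A LINE/L1-like
    chromomethyltransferase-dependent transposon family lives in
    heterochromatin (body = heterochromatic signature, faint edges); a
    RathE1-like RdDM-dependent family lives in the arms (uniform body,
    strong edges). Genotypes: wt, cmt2 (favored CHH x0.2, other CHH x0.8,
    CHG x0.75), nrpe1 (euchromatic CHH x0.15, edges and islands x0.1).
    """
    models = _arabidopsis_site_models()
    het_start = int(chrom_length * 0.4)
    het_end = int(chrom_length * 0.6)
    scale = chrom_length / 2_000_000  # feature counts track genome size
    het_len = het_end - het_start
    arm_len = chrom_length - het_len

    def _fit(n, domain_len, max_len, occupancy=0.5):
        # never ask for more features than half the domain can hold
        return max(1, min(n, int(domain_len * occupancy / max_len)))

    transposons = (
        TransposonFamilyPlan(
            family="LINE/L1", n=_fit(round(30 * scale) or 4, het_len, 5000),
            length_range=(2000, 5000),
            domain="heterochromatin", signature="CMT-like",
            edge_amplitude=0.05, edge_decay_bp=300.0,
            body_models=models["heterochromatin"],
        ),
        TransposonFamilyPlan(
            family="RathE1", n=_fit(round(20 * scale) or 4, arm_len, 3500, 0.3),
            length_range=(1500, 3500),
            domain="euchromatin", signature="RdDM-like",
            edge_amplitude=0.35, edge_decay_bp=300.0,
            body_models=_rddm_body_models(models["euchromatin"]),
        ),
    )
    genotypes = {
        "wt": GenotypeEffect(),
        "cmt2": GenotypeEffect(
            level_multipliers={
                ("*", "CAA"): 0.2, ("*", "CTA"): 0.2,
                ("*", "CHH"): 0.8, ("*", "CHG"): 0.75,
            }
        ),
        "nrpe1": GenotypeEffect(
            level_multipliers={("euchromatin", "CHH"): 0.15},
            edge_multiplier=0.1,
            island_multiplier=0.1,
        ),
    }
    return SimulationConfig(
        seed=seed,
        contigs=(
            ContigPlan("chr1", chrom_length, gc=0.36,
                       het_span=(het_start, het_end)),
            ContigPlan("chloroplast", control_length, gc=0.36,
                       is_control=True),
        ),
        site_models=models,
        coverage_lambda=coverage_lambda,
        conversion_failure=conversion_failure,
        transposons=transposons,
        genes=GenePlan(n=_fit(round(25 * scale) or 4, arm_len, 4000, 0.3),
                       length_range=(1500, 4000),
                       island_amplitude=0.08, island_decay_bp=300.0),
        genotypes=genotypes,
        srna=srna or SrnaPlan(),
    )


def expected_observed_mean(true_mean: float, epsilon: float) -> float:
    """Mean level the sequencer reports for a site population with true mean
    ``true_mean`` under conversion failure ``epsilon``."""
    return true_mean + (1 - true_mean) * epsilon
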