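"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (config, seed) and returns both the
data in the exact in-memory/file dialects the pipeline reads and a truth
table sufficient to score the downstream analysis without re-deriving
ground truth.  The statistical structure mirrors the assays emulated:

* targeted amplicons — template molecules carry true mutations fixed
  across their whole UMI family, reads add independent per-base errors;
* cut-site libraries — per-element Poisson break counts with
  activity-inducible enrichment that scales with binding quartile across a
  stimulation time course, PCR re-reads via a geometric duplication law;
* binding tracks — heavy-tailed per-element intensities over a flat
  control, replicate peak sets with controlled reproducibility;
* single-nucleus expression — log-normal gene baselines with planted
  target-gene downregulation in knockout nuclei and Poisson viral-transcript
  counts.

Default sizes are desk scale: 2 chromosomes x 1 Mb, 200 elements,
30 amplicons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .amplicon import Amplicon, AmpliconPanel, AmpliconRead, BASES, DEL_CODE
from .intervals import GenomicInterval, RegulatoryElement, SignalTrack

__all__ = [
    "GenomeSpec",
    "AmpliconSpec",
    "MutationSpec",
    "DsbSpec",
    "BindingSpec",
    "ExpressionSpec",
    "SimulationConfig",
    "simulate_amplicon_reads",
    "simulate_mutation_cohort",
    "simulate_elements",
    "simulate_signal_tracks",
    "simulate_cut_sites",
    "simulate_expression",
]

CONDITIONS = ("0h", "2h", "10h-less", "10h-still")


@dataclass
class GenomeSpec:
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000})


@dataclass
class AmpliconSpec:
    n_sites: int = 30
    length: int = 122          # 22 bp primer + 100 assessed bp
    primer_len: int = 22
    umi_len: int = 12
    gc: float = 0.5
    bound_fraction: float = 0.5  # fraction of sites labelled TF-bound


@dataclass
class MutationSpec:
    templates_per_site: int = 400
    read_error: float = 0.005          # per-base per-read error rate e
    family_lambda: float = 12.0        # zero-truncated Poisson family size
    base_freq: float = 5e-4            # young per-base true mutation freq
    age_multipliers_unbound: tuple[float, float, float] = (1.0, 2.0, 3.0)
    age_multipliers_bound: tuple[float, float, float] = (1.0, 1.2, 1.4)
    indel_fraction: float = 0.05       # planted mutations that are deletions
    n_animals_per_group: int = 5


@dataclass
class DsbSpec:
    baseline_rate: float = 0.05        # unique events per bp per sample
    # ~50 events per kb-wide element: the depth of a ~10M-read cut-site
    # library spread over a ~2e5-element landscape
    n_replicates: int = 3
    inducible_fraction: float = 0.3
    # fold enrichment at Q4 inducible elements per condition
    fold_profile: dict[str, float] = field(
        default_factory=lambda: {"0h": 1.0, "2h": 3.0,
                                 "10h-less": 1.5, "10h-still": 3.0})
    quartile_weight: dict[str, float] = field(
        default_factory=lambda: {"Q1": 0.0, "Q2": 0.25, "Q3": 0.5, "Q4": 1.0})
    duplication_p: float = 0.5         # PCR re-reads ~ 1 + Geometric(p)
    background_rate: float = 2e-4      # stray events per bp per sample
    batch_multiplier: float = 1.5      # depth offset on second batch
    umi_len: int = 8


@dataclass
class BindingSpec:
    intensity_sigma: float = 1.0       # log-normal binding intensity
    igg_level: float = 1.0
    igg_noise: float = 0.1
    peak_quantile: float = 0.75        # elements above it carry a true peak
    reproducibility: float = 0.7       # per-replicate peak recovery prob
    n_replicates: int = 8
    summit_width: int = 50


@dataclass
class ExpressionSpec:
    n_genes: int = 2000
    n_targets: int = 25
    effect: float = 0.5                # fractional knockdown in Cre nuclei
    n_cre: int = 150
    n_dcre: int = 150
    n_uninfected: int = 100
    baseline_sigma: float = 1.0
    noise_shape: float = 5.0           # gamma noise around gene baseline
    viral_lambda: float = 30.0
    viral_background: float = 0.3
    viral_dropout: float = 0.1
    cell_type: str = "excitatory"


@dataclass
class SimulationConfig:
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    amplicon: AmpliconSpec = field(default_factory=AmpliconSpec)
    mutation: MutationSpec = field(default_factory=MutationSpec)
    dsb: DsbSpec = field(default_factory=DsbSpec)
    binding: BindingSpec = field(default_factory=BindingSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    n_elements: int = 200
    element_half_width: int = 500

    def to_dict(self) -> dict:
        return asdict(self)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def _random_umis(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    codes = rng.integers(0, 4, size=(n, k))
    return np.array(["".join(row) for row in np.array(list(BASES))[codes]])


def _zt_poisson(rng: np.random.Generator, lam: float, n: int) -> np.ndarray:
    sizes = rng.poisson(lam, size=n)
    while (zero := sizes == 0).any():
        sizes[zero] = rng.poisson(lam, size=int(zero.sum()))
    return sizes


# ------------------------------------------------------------- amplicons

def make_panel(cfg: SimulationConfig, seed: int) -> AmpliconPanel:
    """Deterministic amplicon panel: references, coordinates, bound labels."""
    rng = np.random.default_rng(seed)
    a = cfg.amplicon
    amps = {}
    for i in range(a.n_sites):
        aid = f"amp{i:03d}"
        chrom = list(cfg.genome.chrom_sizes)[i % len(cfg.genome.chrom_sizes)]
        start = 10_000 + 5_000 * i
        amps[aid] = Amplicon(aid, chrom, start, start + a.length,
                             _random_seq(rng, a.length, a.gc),
                             primer_len=a.primer_len, umi_len=a.umi_len)
    return AmpliconPanel(amps)


def site_bound_labels(cfg: SimulationConfig) -> dict[str, bool]:
    n = cfg.amplicon.n_sites
    n_bound = round(n * cfg.amplicon.bound_fraction)
    return {f"amp{i:03d}": i < n_bound for i in range(n)}


def simulate_amplicon_reads(cfg: SimulationConfig, seed: int,
                            panel: AmpliconPanel | None = None,
                            site_freq: dict[str, float] | None = None,
                            sample_id: str = "S1",
                            ) -> tuple[AmpliconPanel, list[AmpliconRead], pd.DataFrame]:
    """One sample's aligned amplicon reads plus a planted-mutation truth table.

    Per site, ``templates_per_site`` template molecules are drawn; every
    assessed position of a template mutates independently with the site's
    true frequency (the mutation is then shared by the whole UMI family);
    family sizes follow a zero-truncated Poisson; each read adds
    independent per-base errors at rate ``read_error`` (uniform over the
    three alternative bases).  The truth table records, per site, the
    planted mutated template-positions and the realised per-base planted
    frequency over assessed positions.
    """
    rng = np.random.default_rng(seed)
    m = cfg.mutation
    if panel is None:
        panel = make_panel(cfg, seed=0)
    if site_freq is None:
        site_freq = {amp.amplicon_id: m.base_freq for amp in panel}
    reads: list[AmpliconRead] = []
    truth_rows = []
    for amp in panel:
        mu = site_freq[amp.amplicon_id]
        L, P = amp.length, amp.primer_len
        n_assessed = L - P
        ref_codes = np.array([BASES.index(b) for b in amp.reference],
                             dtype=np.uint8)
        templates = np.broadcast_to(ref_codes, (m.templates_per_site, L)).copy()
        # true mutations only in assessed (non-primer) positions
        mut_mask = np.zeros((m.templates_per_site, L), dtype=bool)
        mut_mask[:, P:] = rng.random((m.templates_per_site, n_assessed)) < mu
        ti, pi = np.nonzero(mut_mask)
        is_del = rng.random(len(ti)) < m.indel_fraction
        shift = rng.integers(1, 4, size=len(ti)).astype(np.uint8)
        templates[ti, pi] = np.where(
            is_del, DEL_CODE, (templates[ti, pi] + shift) % 4)
        sizes = _zt_poisson(rng, m.family_lambda, m.templates_per_site)
        umis = _random_umis(rng, m.templates_per_site, amp.umi_len)
        read_codes = np.repeat(templates, sizes, axis=0)
        err = (rng.random(read_codes.shape) < m.read_error) & (read_codes < 4)
        ei, ep = np.nonzero(err)
        eshift = rng.integers(1, 4, size=len(ei)).astype(np.uint8)
        read_codes[ei, ep] = (read_codes[ei, ep] + eshift) % 4
        read_umis = np.repeat(umis, sizes)
        reads.extend(
            AmpliconRead(amp.amplicon_id, u, row)
            for u, row in zip(read_umis, read_codes))
        truth_rows.append({
            "sample_id": sample_id, "amplicon_id": amp.amplicon_id,
            "true_freq": mu,
            "n_templates": m.templates_per_site,
            "planted_mut_positions": int(mut_mask.sum()),
            "planted_freq": mut_mask[:, P:].sum() / (m.templates_per_site * n_assessed),
            "n_reads": int(sizes.sum())})
    return panel, reads, pd.DataFrame(truth_rows)


def simulate_mutation_cohort(cfg: SimulationConfig, seed: int
                             ) -> tuple[AmpliconPanel, dict[str, list[AmpliconRead]],
                                        pd.DataFrame, pd.DataFrame]:
    """Ageing-gradient cohort: per-animal read sets over one shared panel.

    True per-site frequency = base_freq x age multiplier, with a damped
    multiplier at TF-bound sites.  Returns (panel, reads per animal, animal
    sheet, truth table).
    """
    rng = np.random.default_rng(seed)
    panel = make_panel(cfg, seed=0)
    bound = site_bound_labels(cfg)
    m = cfg.mutation
    sheet_rows, truth, reads_by_animal = [], [], {}
    for gi, age in enumerate(("young", "middle", "old")):
        for ai in range(m.n_animals_per_group):
            animal = f"{age[0].upper()}{ai + 1}"
            freq = {aid: m.base_freq * (m.age_multipliers_bound[gi] if b
                                        else m.age_multipliers_unbound[gi])
                    for aid, b in bound.items()}
            sub_seed = int(rng.integers(0, 2**31 - 1))
            _, reads, t = simulate_amplicon_reads(
                cfg, sub_seed, panel=panel, site_freq=freq, sample_id=animal)
            reads_by_animal[animal] = reads
            t["age_group"] = age
            truth.append(t)
            sheet_rows.append({"animal_id": animal, "age_group": age})
    return (panel, reads_by_animal, pd.DataFrame(sheet_rows),
            pd.concat(truth, ignore_index=True))


# ------------------------------------------------------------- landscape

def simulate_elements(cfg: SimulationConfig, seed: int
                      ) -> list[RegulatoryElement]:
    """Fixed-width, non-overlapping planted regulatory elements."""
    rng = np.random.default_rng(seed)
    chroms = list(cfg.genome.chrom_sizes)
    width = 2 * cfg.element_half_width
    elements = []
    spacing_ok = all(size > cfg.n_elements * 3 * width
                     for size in cfg.genome.chrom_sizes.values())
    if not spacing_ok:
        raise ValueError("genome too small for requested element count")
    per_chrom = np.array_split(np.arange(cfg.n_elements), len(chroms))
    i = 0
    for chrom, idx in zip(chroms, per_chrom):
        size = cfg.genome.chrom_sizes[chrom]
        slots = np.linspace(2 * width, size - 2 * width, num=len(idx),
                            dtype=np.int64)
        jitter = rng.integers(-width // 2, width // 2, size=len(idx))
        for start in slots + jitter:
            iv = GenomicInterval(chrom, int(start), int(start) + width)
            elements.append(RegulatoryElement(
                interval=iv, summit=(iv.start + iv.end) // 2,
                element_id=f"RE{i:06d}"))
            i += 1
    return elements


@dataclass
class BindingTruth:
    intensity: pd.Series            # per-element binding intensity
    quartile: pd.Series             # Q1..Q4 by intensity/IgG ratio rank
    has_peak: pd.Series
    q4_high: pd.Series
    q1_low: pd.Series


def simulate_signal_tracks(cfg: SimulationConfig, seed: int,
                           elements: Sequence[RegulatoryElement] | None = None,
                           ) -> tuple[SignalTrack, SignalTrack,
                                      list[GenomicInterval],
                                      list[list[GenomicInterval]],
                                      BindingTruth]:
    """Binding and control (IgG) tracks, true peaks, replicate peak sets.

    Per-element binding intensity is log-normal (heavy-tailed); each
    element's signal run carries a narrow summit at 2x the element level so
    summit finding is well posed.  Elements above ``peak_quantile`` of
    intensity carry a true peak; each replicate set recovers each true peak
    independently with probability ``reproducibility``.
    """
    rng = np.random.default_rng(seed)
    b = cfg.binding
    if elements is None:
        elements = simulate_elements(cfg, seed)
    ids = [e.element_id for e in elements]
    intensity = np.exp(rng.normal(0.0, b.intensity_sigma, size=len(elements)))
    runs_num, runs_den = [], []
    for e, inten in zip(elements, intensity):
        iv = e.interval
        s0 = e.summit - b.summit_width // 2
        s1 = s0 + b.summit_width
        runs_num += [(iv.chrom, iv.start, s0, inten),
                     (iv.chrom, s0, s1, 2 * inten),
                     (iv.chrom, s1, iv.end, inten)]
        runs_den.append((iv.chrom, iv.start, iv.end,
                         b.igg_level * (1 + b.igg_noise * rng.standard_normal())))
    num_track = SignalTrack(runs_num, cfg.genome.chrom_sizes)
    den = np.array([r[3] for r in runs_den])
    den_track = SignalTrack(runs_den, cfg.genome.chrom_sizes)
    ratio = intensity / np.maximum(den, 1e-9)
    cut = np.quantile(intensity, b.peak_quantile)
    has_peak = intensity >= cut
    true_peaks = [e.interval for e, h in zip(elements, has_peak) if h]
    replicate_sets = []
    for _ in range(b.n_replicates):
        keep = rng.random(len(true_peaks)) < b.reproducibility
        replicate_sets.append([p for p, k in zip(true_peaks, keep) if k])
    order = sorted(range(len(elements)),
                   key=lambda i: (ratio[i], elements[i].interval.chrom,
                                  elements[i].interval.start))
    quart = np.empty(len(elements), dtype=object)
    for rank, i in enumerate(order):
        quart[i] = f"Q{rank * 4 // len(elements) + 1}"
    truth = BindingTruth(
        intensity=pd.Series(intensity, index=ids),
        quartile=pd.Series(quart, index=ids),
        has_peak=pd.Series(has_peak, index=ids),
        q4_high=pd.Series((quart == "Q4") & has_peak, index=ids),
        q1_low=pd.Series((quart == "Q1") & ~has_peak, index=ids))
    return num_track, den_track, true_peaks, replicate_sets, truth


# ------------------------------------------------------------- cut sites

def simulate_cut_sites(cfg: SimulationConfig, seed: int,
                       elements: Sequence[RegulatoryElement] | None = None,
                       binding_truth: BindingTruth | None = None,
                       conditions: Sequence[str] = CONDITIONS,
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                  list[RegulatoryElement]]:
    """Per-sample cut-site read records over a stimulation time course.

    Per element and sample the unique-event count is Poisson with rate
    baseline x width x fold, where fold interpolates the condition's Q4
    enrichment by binding-quartile weight and applies only to truth-
    inducible elements.  Every unique event is re-read 1 + Geometric(p)
    times (PCR duplicates); background events scatter genome-wide.  The
    second half of replicates forms a separate processing batch whose read
    depth is multiplied by ``batch_multiplier`` (all conditions present in
    each batch).

    Returns (records, sample sheet, per-element truth counts, elements).
    """
    rng = np.random.default_rng(seed)
    d = cfg.dsb
    if elements is None:
        elements = simulate_elements(cfg, seed)
    if binding_truth is None:
        *_, binding_truth = simulate_signal_tracks(cfg, seed + 1,
                                                   elements=elements)
    ids = [e.element_id for e in elements]
    inducible = pd.Series(
        np.random.default_rng(seed + 2).random(len(elements))
        < d.inducible_fraction, index=ids)
    all_records, sheet_rows, truth_rows = [], [], []
    for cond in conditions:
        for rep in range(d.n_replicates):
            sample = f"{cond}_r{rep + 1}"
            batch = "B" if rep >= d.n_replicates / 2 else "A"
            depth_mult = d.batch_multiplier if batch == "B" else 1.0
            sheet_rows.append({"sample_id": sample, "condition": cond,
                               "batch": batch})
            recs = []
            for e in elements:
                q = binding_truth.quartile[e.element_id]
                fold = 1.0
                if inducible[e.element_id]:
                    fold += (d.fold_profile[cond] - 1.0) * d.quartile_weight[q]
                lam = d.baseline_rate * e.interval.width * fold * depth_mult
                n_ev = rng.poisson(lam)
                truth_rows.append({"element_id": e.element_id,
                                   "sample_id": sample, "condition": cond,
                                   "batch": batch, "fold": fold,
                                   "n_true_events": int(n_ev)})
                if n_ev == 0:
                    continue
                pos = rng.integers(e.interval.start, e.interval.end, size=n_ev)
                recs.append(pd.DataFrame({
                    "chrom": e.interval.chrom, "pos": pos,
                    "strand": np.where(rng.random(n_ev) < 0.5, "+", "-"),
                    "umi": _random_umis(rng, n_ev, d.umi_len)}))
            # genome-wide background
            for chrom, size in cfg.genome.chrom_sizes.items():
                n_bg = rng.poisson(d.background_rate * size * depth_mult)
                if n_bg:
                    recs.append(pd.DataFrame({
                        "chrom": chrom,
                        "pos": rng.integers(0, size, size=n_bg),
                        "strand": np.where(rng.random(n_bg) < 0.5, "+", "-"),
                        "umi": _random_umis(rng, n_bg, d.umi_len)}))
            ev = pd.concat(recs, ignore_index=True)
            # numpy's geometric has support {1,2,...}: exactly 1 + Geometric0(p)
            n_copies = rng.geometric(d.duplication_p, size=len(ev))
            dup = ev.loc[ev.index.repeat(n_copies)].reset_index(drop=True)
            dup["sample_id"] = sample
            all_records.append(dup)
    records = pd.concat(all_records, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    truth["inducible"] = truth["element_id"].map(inducible)
    truth["quartile"] = truth["element_id"].map(binding_truth.quartile)
    return records, pd.DataFrame(sheet_rows), truth, list(elements)


# ------------------------------------------------------------ expression

def simulate_expression(cfg: SimulationConfig, seed: int
                        ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Normalized single-nucleus expression with planted target knockdown.

    Gene baselines are log-normal; per-nucleus values are gamma noise
    around the baseline (continuous, non-negative, mimicking log-normalized
    counts).  Target genes are drawn from the top expression decile and
    multiplied by (1 - effect) in Cre (knockout) nuclei.  Viral transcript
    counts are Poisson with dropout for the carried virus and a low
    background for the other.

    Returns (expr genes x nuclei, per-nucleus metadata, truth dict).
    """
    rng = np.random.default_rng(seed)
    x = cfg.expression
    genes = [f"gene{i:04d}" for i in range(x.n_genes)]
    baseline = np.exp(rng.normal(0.0, x.baseline_sigma, size=x.n_genes))
    n_total = x.n_cre + x.n_dcre + x.n_uninfected
    labels = (["Cre"] * x.n_cre + ["dCre"] * x.n_dcre
              + ["uninfected"] * x.n_uninfected)
    nuclei = [f"cell{i:04d}" for i in range(n_total)]
    top_decile = np.argsort(baseline)[::-1][: max(x.n_genes // 10, x.n_targets)]
    targets = sorted(np.array(genes)[
        rng.choice(top_decile, size=x.n_targets, replace=False)])
    shape = x.noise_shape
    expr = rng.gamma(shape, scale=baseline[:, None] / shape,
                     size=(x.n_genes, n_total))
    is_target = np.isin(genes, targets)
    is_cre = np.array(labels) == "Cre"
    expr[np.ix_(is_target, is_cre)] *= (1.0 - x.effect)
    mch = np.where(is_cre,
                   rng.poisson(x.viral_lambda, n_total),
                   rng.poisson(x.viral_background, n_total))
    gfp = np.where(np.array(labels) == "dCre",
                   rng.poisson(x.viral_lambda, n_total),
                   rng.poisson(x.viral_background, n_total))
    dropout = rng.random(n_total) < x.viral_dropout
    mch = np.where(dropout & is_cre, 0, mch)
    meta = pd.DataFrame({
        "cell_type": x.cell_type, "true_infection": labels,
        "mCherry": mch, "GFP": gfp}, index=pd.Index(nuclei, name="nucleus"))
    truth = {"targets": targets, "effect": x.effect,
             "baseline": pd.Series(baseline, index=genes)}
    return (pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                         columns=nuclei), meta, truth)
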