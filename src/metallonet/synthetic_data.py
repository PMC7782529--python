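"""Synthetic inputs for the whole pipeline.

Every input the analysis consumes — a protein interactome, metal→protein
annotations, an abstract corpus, multi-dataset case/control expression
matrices with batch effects, and a cohort table of serum/CSF metal
concentrations and qPCR Ct values — can be generated here with the
statistical structure the downstream methods assume:

* the interactome is a planted-partition graph (dense communities over a
  sparse background) so cohesiveness clustering has real structure to find;
* expression datasets share per-gene baselines, carry additive per-dataset
  batch offsets, and shift a planted subset of genes in cases with a
  consistent sign across datasets;
* the corpus co-mentions designated disease proteins with the disease term
  at a configured enrichment odds;
* cohort analytes are drawn from group-wise truncated-normal marginals whose
  default means/SDs are the published serum (n=87/87) and CSF (n=42/42)
  Parkinson's cohort summaries, linked by a Gaussian copula when correlations
  are configured.

Every generator is a pure function of its configuration (which carries the
seed): the same config yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    GROUP_CASE,
    GROUP_CONTROL,
    CohortTable,
    ExpressionStudy,
    InteractionGraph,
    MetalProteinTable,
    SummaryStats,
    logger,
)

DISEASE_TERMS = ("Parkinson's disease",)

METAL_NAMES = (
    "COPPER", "IRON", "CALCIUM", "MAGNESIUM", "ALUMINUM", "ZINC",
    "MANGANESE", "POTASSIUM", "SODIUM", "NICKEL", "COBALT", "CESIUM",
    "TUNGSTEN", "MOLYBDENUM", "CADMIUM", "CHROMIUM",
)


@dataclass(frozen=True)
class GroupStats:
    """Control/case summary pair for one measured analyte."""

    control: SummaryStats
    case: SummaryStats


def _s(mean: float, sd: float, n: int) -> SummaryStats:
    return SummaryStats(mean=mean, sd=sd, n=n)


#: Published cohort summaries (ug/L): serum n=87 per group, CSF n=42 per group.
#: These are the gen_cohort defaults and the inputs to the analytic t-tests.
REFERENCE_METAL_SUMMARIES: dict[str, GroupStats] = {
    "serum_aluminum": GroupStats(_s(4.11, 1.52, 87), _s(4.755, 1.4, 87)),
    "serum_calcium": GroupStats(_s(64825, 1514, 87), _s(72303, 1720, 87)),
    "serum_copper": GroupStats(_s(1133, 127, 87), _s(909, 337, 87)),
    "serum_iron": GroupStats(_s(1265, 439, 87), _s(1091, 434, 87)),
    "serum_magnesium": GroupStats(_s(20031, 1923, 87), _s(21276, 1915, 87)),
    "csf_aluminum": GroupStats(_s(3.12, 0.886, 42), _s(2.43, 1.42, 42)),
    "csf_calcium": GroupStats(_s(26291.15, 5411.9, 42), _s(28447.38, 3378.10, 42)),
    "csf_copper": GroupStats(_s(27, 4.78, 42), _s(24.4, 8.06, 42)),
    "csf_iron": GroupStats(_s(221, 28, 42), _s(172, 83.8, 42)),
    "csf_magnesium": GroupStats(_s(23030, 2659, 42), _s(25466, 3512, 42)),
}

#: Published p-value bounds printed alongside the cohort summary table.
REFERENCE_P_BOUNDS: dict[str, float] = {
    "serum_aluminum": 0.02,
    "serum_calcium": 0.001,
    "serum_copper": 0.001,
    "serum_iron": 0.009,
    "serum_magnesium": 0.0006,
    "csf_aluminum": 0.03,
    "csf_calcium": 0.03,
    "csf_copper": 0.029,
    "csf_iron": 0.002,
    "csf_magnesium": 0.00055,
}

#: qPCR Ct summaries (cycles).  ACTB is the housekeeping reference.  Target
#: genes are shifted ~1 cycle down in PD (upregulation, fold ~2) except SOD1,
#: shifted up (downregulation), mirroring the cohort's qPCR findings.
REFERENCE_CT_SUMMARIES: dict[str, GroupStats] = {
    "ct_ACTB": GroupStats(_s(18.0, 0.5, 87), _s(18.0, 0.5, 87)),
    "ct_B2M": GroupStats(_s(24.0, 1.0, 87), _s(23.0, 1.0, 87)),
    "ct_TARDBP": GroupStats(_s(25.0, 1.0, 87), _s(24.0, 1.0, 87)),
    "ct_EFEMP2": GroupStats(_s(26.0, 1.0, 87), _s(25.0, 1.0, 87)),
    "ct_MMP9": GroupStats(_s(24.5, 1.0, 87), _s(23.5, 1.0, 87)),
    "ct_MEAF2A": GroupStats(_s(26.5, 1.0, 87), _s(25.5, 1.0, 87)),
    "ct_SOD1": GroupStats(_s(22.0, 1.0, 87), _s(23.0, 1.0, 87)),
    "ct_CRP": GroupStats(_s(27.0, 1.2, 87), _s(26.0, 1.2, 87)),
}

#: Default copula links: same-metal serum/CSF coupling plus the
#: copper-concentration / B2M-expression interdependency (lower copper with
#: higher B2M expression, i.e. lower Ct with lower copper).
DEFAULT_CORRELATIONS: tuple[tuple[str, str, float], ...] = (
    ("serum_copper", "csf_copper", 0.5),
    ("serum_iron", "csf_iron", 0.5),
    ("serum_copper", "ct_B2M", 0.5),
)


@dataclass(frozen=True)
class SynthesisConfig:
    """Parameters of the synthetic workspace.

    Defaults emulate the study design: a structured interactome with
    communities large enough to survive the minimum-group-size filter,
    several metal groups (a few deliberately under-sized), five case/control
    expression datasets of 20 vs 20 samples with batch offsets and a planted
    differentially expressed gene subset at a 2-fold log2 effect, an
    abstract corpus with 8:1 disease-co-mention odds for designated disease
    proteins, and the published cohort summary statistics.
    """

    seed: int = 0
    n_proteins: int = 220
    n_metals: int = 12
    community_sizes: tuple[int, ...] = (14, 13, 12, 12, 11, 11, 10, 10, 10, 10)
    background_p: float = 0.02
    within_p: float = 0.9
    n_signal_communities: int = 3
    n_datasets: int = 5
    samples_per_group: int = 20
    n_genes: int | None = None          # None -> one gene per protein
    de_fraction: float = 0.15
    de_effect: float = 2.0              # log2 units
    noise_sd: float = 1.0
    batch_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    corpus_size: int = 6000
    disease_doc_p: float = 0.3
    symbol_mention_p: float = 0.0003
    enrichment_odds: float = 50.0
    metal_summaries: Mapping[str, GroupStats] = field(
        default_factory=lambda: dict(REFERENCE_METAL_SUMMARIES))
    ct_summaries: Mapping[str, GroupStats] = field(
        default_factory=lambda: dict(REFERENCE_CT_SUMMARIES))
    correlations: tuple[tuple[str, str, float], ...] = DEFAULT_CORRELATIONS

    def __post_init__(self) -> None:
        for p in (self.background_p, self.within_p, self.disease_doc_p,
                  self.symbol_mention_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.within_p <= self.background_p:
            raise ValueError("within-community probability must exceed background")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("DE fraction outside [0, 1]")
        if self.de_effect <= 0:
            raise ValueError("DE effect size must be > 0")
        if self.enrichment_odds <= 1:
            raise ValueError("enrichment odds must be > 1")
        if sum(self.community_sizes) > self.n_proteins:
            raise ValueError("community sizes sum exceeds n_proteins")

    def with_seed(self, seed: int) -> "SynthesisConfig":
        return replace(self, seed=seed)


def protein_names(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def community_assignment(config: SynthesisConfig) -> list[set[str]]:
    """Planted communities as protein-name sets (deterministic, seed-free)."""
    names = protein_names(config.n_proteins)
    out, start = [], 0
    for size in config.community_sizes:
        out.append(set(names[start:start + size]))
        start += size
    return out


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------

def gen_ppi(config: SynthesisConfig) -> InteractionGraph:
    """Planted-partition interactome: dense blocks on community members,
    Bernoulli background elsewhere."""
    rng = np.random.default_rng(config.seed)
    names = protein_names(config.n_proteins)
    comm = np.full(config.n_proteins, -1)
    start = 0
    for ci, size in enumerate(config.community_sizes):
        comm[start:start + size] = ci
        start += size
    n = config.n_proteins
    iu, ju = np.triu_indices(n, k=1)
    same = (comm[iu] == comm[ju]) & (comm[iu] >= 0)
    p = np.where(same, config.within_p, config.background_p)
    draw = rng.random(len(p)) < p
    edges = [(names[i], names[j]) for i, j in zip(iu[draw], ju[draw])]
    return InteractionGraph.from_edges(edges, nodes=names, label="metal", name="synthetic_ppi")


def gen_metal_annotations(config: SynthesisConfig,
                          graph: InteractionGraph) -> MetalProteinTable:
    """Metal → binding-protein table over the interactome nodes.

    The first metals take one planted community each as their binding set,
    plus one member of another community of the same disease status (so some
    proteins are multi-metal without bridging signal and noise groups).
    Remaining metals get small background sets below the downstream
    minimum-group-size threshold of 10, exercising the filter; surviving
    metal groups are thus all module-based, mirroring the functional
    coherence of real metal-binding protein families.
    """
    if graph.n_nodes() == 0:
        raise ValueError("interactome is empty")
    rng = np.random.default_rng(config.seed + 1)
    communities = community_assignment(config)
    names = sorted(graph.nodes)
    background = sorted(set(names) - set().union(*communities)) if communities else names
    table = MetalProteinTable()
    metals = [METAL_NAMES[i % len(METAL_NAMES)] + ("" if i < len(METAL_NAMES) else str(i))
              for i in range(config.n_metals)]
    n_sig = config.n_signal_communities
    for i, metal in enumerate(metals):
        if i < len(communities):
            members = set(communities[i])
            # multi-metal assignment: borrow one protein from the next
            # community of the same (disease / background) status, so shared
            # proteins never bridge planted-signal and noise groups
            if i < n_sig:
                donor = communities[(i + 1) % n_sig]
            else:
                rest = len(communities) - n_sig
                donor = communities[n_sig + (i - n_sig + 1) % rest]
            members.add(min(donor))
        else:
            # sparse background metal, deliberately below the min-10
            # threshold so the group-size filter has something to drop
            size = min(6 + (i - len(communities)) % 3, len(background))
            picked = rng.choice(background, size=size, replace=False)
            members = set(picked)
        for prot in members:
            table.add(metal, prot)
    return table


# ---------------------------------------------------------------------------
# Literature corpus
# ---------------------------------------------------------------------------

def gen_corpus(config: SynthesisConfig, pd_proteins: set[str],
               all_symbols: set[str]) -> dict[str, str]:
    """Abstract corpus with configured disease/protein co-mention enrichment.

    Each document is a short text that may mention the disease term and a
    handful of protein symbols.  Non-disease proteins are mentioned
    independently of the disease term; designated disease proteins are
    mentioned ``enrichment_odds`` times more often in disease documents.
    Raises if the corpus is too small to give every disease protein at least
    three co-mention documents.
    """
    if not pd_proteins <= all_symbols:
        raise ValueError("pd_proteins must be a subset of all_symbols")
    rng = np.random.default_rng(config.seed + 2)
    symbols = sorted(all_symbols)
    pd_idx = np.array([i for i, s in enumerate(symbols) if s in pd_proteins],
                      dtype=int)
    base_p = config.symbol_mention_p
    enriched_p = min(0.95, base_p * config.enrichment_odds)
    expected_cooc = config.corpus_size * config.disease_doc_p * enriched_p
    if expected_cooc < 10:
        raise ValueError(
            f"corpus too small: expected disease co-mentions per protein "
            f"{expected_cooc:.1f} cannot guarantee the >=3-abstract minimum")
    n_docs = config.corpus_size
    is_disease = rng.random(n_docs) < config.disease_doc_p
    prob = np.full((n_docs, len(symbols)), base_p)
    if len(pd_idx):
        prob[np.ix_(is_disease, pd_idx)] = enriched_p
    mention = rng.random((n_docs, len(symbols))) < prob
    if len(pd_idx):
        cooc = mention[is_disease][:, pd_idx].sum(axis=0)
        short = [symbols[i] for i, c in zip(pd_idx, cooc) if c < 3]
        if short:
            raise ValueError(
                f"corpus size {config.corpus_size} left disease proteins "
                f"below the 3-abstract minimum: {short}")
    filler = ("study", "of", "the", "brain", "catalogue", "cohort",
              "neurodegeneration", "analysis")
    sym_arr = np.array(symbols)
    corpus: dict[str, str] = {}
    for d in range(n_docs):
        words = list(rng.choice(filler, size=4))
        mentioned = sym_arr[mention[d]]
        text = " ".join(words)
        if len(mentioned):
            text += " " + " ".join(mentioned)
        if is_disease[d]:
            text += " in " + DISEASE_TERMS[0]
        corpus[f"DOC{d:05d}"] = text.strip()
    return corpus


# ---------------------------------------------------------------------------
# Expression datasets
# ---------------------------------------------------------------------------

def gen_expression(config: SynthesisConfig, genes: Sequence[str],
                   de_genes: set[str]) -> list[ExpressionStudy]:
    """Multi-dataset case/control expression with planted signal.

    Per dataset: Gaussian log2 intensities around shared per-gene baselines,
    an additive per-dataset, per-gene batch offset (SD ``batch_sd``), and the
    planted genes shifted by ±``de_effect`` in cases with a sign that is
    consistent across datasets.
    """
    genes = [str(g) for g in genes]
    if not set(de_genes) <= set(genes):
        raise ValueError("de_genes must be a subset of genes")
    if config.samples_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    master = np.random.default_rng(config.seed + 3)
    baseline = config.baseline_mean + config.baseline_sd * master.standard_normal(len(genes))
    signs = master.choice([-1.0, 1.0], size=len(genes))
    de_mask = np.array([g in de_genes for g in genes])
    studies = []
    npg = config.samples_per_group
    for d in range(config.n_datasets):
        rng = np.random.default_rng(master.integers(0, 2**31))
        batch_offset = config.batch_sd * rng.standard_normal(len(genes))
        cols, data = [], []
        groups = {}
        for gi, group in enumerate((GROUP_CONTROL, GROUP_CASE)):
            for s in range(npg):
                name = f"DS{d}_{group}_{s:02d}"
                vals = baseline + batch_offset + config.noise_sd * rng.standard_normal(len(genes))
                if group == GROUP_CASE:
                    vals = vals + de_mask * signs * config.de_effect
                cols.append(name)
                data.append(vals)
                groups[name] = group
        matrix = pd.DataFrame(np.array(data).T, index=genes, columns=cols)
        studies.append(ExpressionStudy(
            matrix=matrix,
            groups=pd.Series(groups),
            batch=pd.Series({c: f"DS{d}" for c in cols}),
            platform=f"synthetic dataset {d}",
            normalized=True,
        ))
    return studies


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

def _build_correlation_matrix(columns: list[str],
                              pairs: Sequence[tuple[str, str, float]]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(columns)}
    C = np.eye(len(columns))
    for a, b, rho in pairs:
        if a in idx and b in idx:
            C[idx[a], idx[b]] = C[idx[b], idx[a]] = rho
    eig = np.linalg.eigvalsh(C)
    if eig.min() < -1e-10:
        raise ValueError(
            f"requested correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eig.min():.3g})")
    return C


def gen_cohort(config: SynthesisConfig) -> CohortTable:
    """Cohort of per-subject metal concentrations and qPCR Ct values.

    Marginals are group-wise normals (concentrations truncated at zero; the
    published coefficients of variation are small enough that truncation bias
    is negligible), linked by a Gaussian copula carrying the configured
    pairwise correlations.  Serum and Ct columns are measured on every
    subject; CSF columns only on the CSF subcohort (NaN elsewhere).
    """
    rng = np.random.default_rng(config.seed + 4)
    specs: dict[str, GroupStats] = {**config.metal_summaries, **config.ct_summaries}
    columns = list(specs)
    C = _build_correlation_matrix(columns, config.correlations)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(columns)))
    frames = []
    for group in (GROUP_CONTROL, GROUP_CASE):
        n_total = max(getattr(specs[c], "control" if group == GROUP_CONTROL else "case").n
                      for c in columns)
        z = rng.standard_normal((n_total, len(columns))) @ L.T
        u = stats.norm.cdf(z)
        cols = {}
        for j, c in enumerate(columns):
            s: SummaryStats = getattr(specs[c], "control" if group == GROUP_CONTROL else "case")
            if c.startswith("ct_"):
                vals = s.mean + s.sd * stats.norm.ppf(u[:, j])
            else:
                a = (0.0 - s.mean) / s.sd if s.sd > 0 else -np.inf
                vals = stats.truncnorm.ppf(u[:, j], a=a, b=np.inf,
                                           loc=s.mean, scale=s.sd)
            vals = vals[:n_total].copy()
            vals[s.n:] = np.nan        # analyte measured on its subcohort only
            cols[c] = vals
        frame = pd.DataFrame(cols)
        frame.insert(0, "group", group)
        frame.insert(0, "subject", [f"{group}_{i:03d}" for i in range(n_total)])
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    return CohortTable(data)


# ---------------------------------------------------------------------------
# Whole-workspace convenience
# ---------------------------------------------------------------------------

@dataclass
class SyntheticWorkspace:
    """Everything the pipeline needs, generated from one config."""

    config: SynthesisConfig
    ppi: InteractionGraph
    annotations: MetalProteinTable
    communities: list[set[str]]
    pd_proteins: set[str]
    de_genes: set[str]
    corpus: dict[str, str]
    studies: list[ExpressionStudy]
    cohort: CohortTable
    pathways: dict[str, set[str]]


def gen_workspace(config: SynthesisConfig) -> SyntheticWorkspace:
    """Generate the full synthetic study.

    The first ``n_signal_communities`` planted communities are the
    disease-associated ones: their members are both literature-enriched
    (corpus) and differentially expressed (expression datasets), so the
    end-to-end pipeline has a planted truth to recover.
    """
    ppi = gen_ppi(config)
    annotations = gen_metal_annotations(config, ppi)
    communities = community_assignment(config)
    signal = communities[:config.n_signal_communities]
    pd_proteins = set().union(*signal) if signal else set()
    genes = sorted(ppi.nodes)
    de_genes = set(pd_proteins)
    extra_needed = max(0, int(round(config.de_fraction * len(genes))) - len(de_genes))
    non_signal = [g for g in genes if g not in de_genes]
    rng = np.random.default_rng(config.seed + 5)
    if extra_needed:
        de_genes |= set(rng.choice(non_signal, size=min(extra_needed, len(non_signal)),
                                   replace=False))
    corpus = gen_corpus(config, pd_proteins, set(genes))
    studies = gen_expression(config, genes, de_genes)
    cohort = gen_cohort(config)
    # pathway gene sets: planted communities under pathway-style names, for
    # the pathway comparison networks and the enrichment/prioritizer stages
    pathways = {f"PATHWAY_{i:02d}": set(c) for i, c in enumerate(communities)}
    logger.info("synthetic workspace: %d proteins, %d metals, %d datasets, "
                "%d abstracts", config.n_proteins, config.n_metals,
                config.n_datasets, config.corpus_size)
    return SyntheticWorkspace(
        config=config, ppi=ppi, annotations=annotations,
        communities=communities, pd_proteins=pd_proteins, de_genes=de_genes,
        corpus=corpus, studies=studies, cohort=cohort, pathways=pathways,
    )
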