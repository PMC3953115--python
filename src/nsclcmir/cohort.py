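"""Synthetic NSCLC cohorts with planted subtype effects and miRNA repression.

The generator emulates the two study designs the pipeline targets:

* a **training** cohort (default 25 SCC + 19 AD tumours) profiled with
  two-channel arrays (log10 sample-vs-pool ratios) and miRNA qPCR cards, and
* a **validation** cohort (default 17 SCC + 24 AD) with paired
  tumour/adjacent-normal tissue assayed by qPCR for both miRNAs and mRNAs.

Planted structure is recorded in a :class:`PlantedTruth` so every downstream
stage (differential expression, signature extraction, network integration,
anti-correlation screening, diagnostics) can be scored against ground truth.

Model in brief
--------------
Arrays: log10 ratio of each gene is Normal(0, sigma_lr^2); planted genes gain
their effect (log10 units; 0.301 = 2-fold) in the over-expressing subtype.

qPCR: each miRNA has a latent per-patient expression deviation
``e = effect * [tumour of the up-subtype] + Normal(0, bio_sd^2)`` (Ct units;
positive e = more abundant); observed replicate Ct = base - e + Normal(0,
sigma_ct^2).  A true pair (m, g, slope) makes the gene's Ct *increase*
linearly with the miRNA's latent expression (repression); such genes receive
their subtype difference only through that coupling.  Non-coupled planted
genes get their own Ct shift (log10 effect converted via log2(10)).
Patient-level mRNA noise is a fixed multiple of sigma_ct, so sigma_ct = 0
makes a coupled gene a deterministic monotone function of its miRNA
(Spearman rho exactly -1 on the expression scale).

Undetermined observations are emitted as the literal instrument token (never
as Ct 40): for each (assay, fraction) entry, a deterministic count
``round(fraction * n_samples)`` of samples loses all replicates of that assay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import CtTable, ExpressionMatrix, TargetTable

__all__ = [
    "SUBTYPES",
    "CohortDesign",
    "PlantedTruth",
    "TRAINING_DESIGN",
    "VALIDATION_DESIGN",
    "gene_universe",
    "mirna_universe",
    "default_truth",
    "truth_target_table",
    "generate_mrna_arrays",
    "generate_ct_tables",
    "write_truth",
    "read_truth",
]

SUBTYPES = ("SCC", "AD")

MIRNA_REFERENCE = "RNU48"
MRNA_REFERENCES = ("B2M", "ACTB", "GAPDH")

#: housekeeping assays: base Ct and patient-level sd expressed as a multiple
#: of noise_sd_ct (B2M deliberately most stable; everything vanishes when
#: noise_sd_ct = 0 so noise-free cohorts are exactly deterministic)
_HOUSEKEEPING = {
    MIRNA_REFERENCE: (24.0, 1.0 / 6.0),
    "B2M": (20.0, 1.0 / 3.0),
    "ACTB": (21.0, 2.0),
    "GAPDH": (22.0, 10.0 / 3.0),
}

#: patient-level mRNA biological noise, as a multiple of noise_sd_ct
GENE_NOISE_RATIO = 3.0

LOG2_10 = np.log2(10.0)


@dataclass(frozen=True)
class CohortDesign:
    """Sample sizes and assay layout of one synthetic cohort."""

    n_scc: int = 25
    n_ad: int = 19
    paired_normals: bool = False
    n_genes: int = 2000
    n_mirnas: int = 100
    n_replicates: int = 3
    seed: int = 0
    cohort: str = "training"

    def __post_init__(self) -> None:
        if self.n_scc < 2 or self.n_ad < 2:
            raise ConfigurationError("need at least 2 patients per subtype")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.n_genes < 1 or self.n_mirnas < 1:
            raise ConfigurationError("gene/miRNA counts must be positive")

    @property
    def n_patients(self) -> int:
        return self.n_scc + self.n_ad


#: designs mirroring the two study cohorts
TRAINING_DESIGN = CohortDesign(n_scc=25, n_ad=19, paired_normals=False,
                               cohort="training")
VALIDATION_DESIGN = CohortDesign(n_scc=17, n_ad=24, paired_normals=True,
                                 cohort="validation")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted into a synthetic cohort.

    ``de_genes``: (gene, up-subtype, effect in log10 units);
    ``de_mirnas``: (miRNA, up-subtype, effect in Ct units);
    ``true_pairs``: (miRNA, gene, repression slope in Ct per Ct-unit of
    latent miRNA expression); ``decoy_pairs``: predicted but not causal.
    """

    de_genes: tuple[tuple[str, str, float], ...] = ()
    de_mirnas: tuple[tuple[str, str, float], ...] = ()
    true_pairs: tuple[tuple[str, str, float], ...] = ()
    decoy_pairs: tuple[tuple[str, str], ...] = ()
    noise_sd_logratio: float = 0.1
    noise_sd_ct: float = 0.3
    mirna_biological_sd: float = 1.0
    undetermined: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.noise_sd_logratio < 0 or self.noise_sd_ct < 0:
            raise ConfigurationError("noise sds must be non-negative")
        if self.mirna_biological_sd < 0:
            raise ConfigurationError("mirna_biological_sd must be non-negative")
        gene_dir = {}
        for gene, sub, eff in self.de_genes:
            _check_subtype(sub)
            if eff < 0:
                raise ConfigurationError(f"negative effect for gene {gene!r}")
            gene_dir[gene] = sub
        mirna_dir = {}
        for mirna, sub, eff in self.de_mirnas:
            _check_subtype(sub)
            if eff < 0:
                raise ConfigurationError(f"negative effect for miRNA {mirna!r}")
            mirna_dir[mirna] = sub
        for mirna, gene, slope in self.true_pairs:
            if mirna not in mirna_dir:
                raise ConfigurationError(
                    f"true pair references non-planted miRNA {mirna!r}")
            if gene not in gene_dir:
                raise ConfigurationError(
                    f"true pair references non-planted gene {gene!r}")
            if mirna_dir[mirna] == gene_dir[gene]:
                raise ConfigurationError(
                    f"pair ({mirna!r}, {gene!r}) violates the repression rule:"
                    " miRNA and target share the up-subtype")
            if slope < 0:
                raise ConfigurationError("repression slopes must be >= 0")
        for assay, frac in self.undetermined:
            if not 0 <= frac <= 1:
                raise ConfigurationError(
                    f"undetermined fraction for {assay!r} outside [0, 1]")

    def gene_directions(self) -> dict[str, str]:
        return {g: s for g, s, _ in self.de_genes}

    def mirna_directions(self) -> dict[str, str]:
        return {m: s for m, s, _ in self.de_mirnas}

    def pair_parents(self) -> dict[str, list[tuple[str, float]]]:
        """Map gene -> [(miRNA, slope)] over the true pairs."""
        out: dict[str, list[tuple[str, float]]] = {}
        for mirna, gene, slope in self.true_pairs:
            out.setdefault(gene, []).append((mirna, slope))
        return out


def _check_subtype(sub: str) -> None:
    if sub not in SUBTYPES:
        raise ConfigurationError(f"unknown subtype {sub!r}; expected {SUBTYPES}")


def gene_universe(design: CohortDesign) -> list[str]:
    return [f"G{i:04d}" for i in range(1, design.n_genes + 1)]


def mirna_universe(design: CohortDesign) -> list[str]:
    return [f"miR-sim-{i:03d}" for i in range(1, design.n_mirnas + 1)]


# in-degree profile of the published 19-edge network: 8 SCC-up miRNAs hitting
# 8 genes (one gene of degree 4, two of degree 3, one of degree 2) plus one
# AD-up miRNA hitting 3 genes
_TRUE_PAIR_LAYOUT = [
    (0, [0, 1, 2, 3, 4]),
    (1, [5, 6, 0]),
    (2, [7]),
    (3, [7]),
    (4, [7]),
    (5, [5, 6, 0]),
    (6, [6]),
    (7, [0]),
]


def default_truth(design: CohortDesign,
                  n_de_genes: int = 50,
                  gene_effect: float = 0.5,
                  n_de_mirnas: int = 9,
                  mirna_effect: float = 2.0,
                  slope: float = 0.4,
                  n_decoy_pairs: int = 10,
                  noise_sd_logratio: float = 0.1,
                  noise_sd_ct: float = 0.3,
                  undetermined: tuple[tuple[str, float], ...] = ()) -> PlantedTruth:
    """Standard planted configuration for the study-sized synthetic cohorts.

    50 DE genes at 0.5 log10 (half up in each subtype), 9 DE miRNAs at 2 Ct
    (8 up in SCC, 1 up in AD, mirroring the published split), 19 true
    repression pairs laid out with the published in-degree profile, and
    decoy predictions pointing at genes with no planted signal.
    """
    genes = gene_universe(design)
    mirnas = mirna_universe(design)
    if n_de_genes > len(genes) - n_decoy_pairs:
        raise ConfigurationError("n_de_genes exceeds the gene universe")
    if n_de_mirnas > len(mirnas):
        raise ConfigurationError("n_de_mirnas exceeds the miRNA universe")
    half = n_de_genes // 2
    de_genes = tuple(
        (g, "AD" if i < half else "SCC", gene_effect)
        for i, g in enumerate(genes[:n_de_genes])
    )
    de_mirnas = tuple(
        (m, "SCC" if i < n_de_mirnas - 1 else "AD", mirna_effect)
        for i, m in enumerate(mirnas[:n_de_mirnas])
    )
    ad_up_genes = [g for g, s, _ in de_genes if s == "AD"]
    scc_up_genes = [g for g, s, _ in de_genes if s == "SCC"]
    true_pairs: list[tuple[str, str, float]] = []
    for mi, gene_ids in _TRUE_PAIR_LAYOUT[: max(0, n_de_mirnas - 1)]:
        for gi in gene_ids:
            true_pairs.append((mirnas[mi], ad_up_genes[gi], slope))
    # the AD-up miRNA represses three SCC-up genes
    for gi in range(3):
        true_pairs.append((mirnas[n_de_mirnas - 1], scc_up_genes[gi], slope))
    null_genes = genes[n_de_genes:n_de_genes + n_decoy_pairs]
    decoys = tuple(
        (mirnas[i % n_de_mirnas], g) for i, g in enumerate(null_genes)
    )
    return PlantedTruth(
        de_genes=de_genes,
        de_mirnas=de_mirnas,
        true_pairs=tuple(true_pairs),
        decoy_pairs=decoys,
        noise_sd_logratio=noise_sd_logratio,
        noise_sd_ct=noise_sd_ct,
        undetermined=tuple(undetermined),
    )


_PROGRAM_CYCLE = (
    frozenset({"miRanda", "TargetScan", "miRWalk"}),
    frozenset({"miRanda", "TargetScan"}),
    frozenset({"miRanda"}),
)


def truth_target_table(truth: PlantedTruth) -> TargetTable:
    """Prediction table implied by the truth: true pairs plus decoys.

    Program annotations cycle deterministically through the three predictor
    sets (content is irrelevant downstream unless a min-programs filter is
    applied); decoys carry a single program.
    """
    mirna_dir = truth.mirna_directions()
    rows = []
    for i, (mirna, gene, _) in enumerate(truth.true_pairs):
        rows.append({"mirna": mirna, "gene": gene,
                     "programs": _PROGRAM_CYCLE[i % 3],
                     "direction": mirna_dir[mirna]})
    for mirna, gene in truth.decoy_pairs:
        rows.append({"mirna": mirna, "gene": gene,
                     "programs": frozenset({"miRWalk"}),
                     "direction": mirna_dir.get(mirna)})
    data = pd.DataFrame(rows, columns=["mirna", "gene", "programs", "direction"])
    return TargetTable(data=data)


# ---------------------------------------------------------------------------
# sample sheets


def _sample_frame(design: CohortDesign) -> pd.DataFrame:
    patients = [f"{design.cohort}-SCC-{i:02d}" for i in range(1, design.n_scc + 1)]
    patients += [f"{design.cohort}-AD-{i:02d}" for i in range(1, design.n_ad + 1)]
    subtypes = ["SCC"] * design.n_scc + ["AD"] * design.n_ad
    return pd.DataFrame({"patient_id": patients, "subtype": subtypes})


def _check_truth_features(design: CohortDesign, truth: PlantedTruth) -> None:
    genes = set(gene_universe(design))
    mirnas = set(mirna_universe(design))
    for gene, _, _ in truth.de_genes:
        if gene not in genes:
            raise ConfigurationError(
                f"planted gene {gene!r} not in the design's gene universe")
    for mirna, _, _ in truth.de_mirnas:
        if mirna not in mirnas:
            raise ConfigurationError(
                f"planted miRNA {mirna!r} not in the design's miRNA universe")
    known_assays = genes | mirnas | set(_HOUSEKEEPING)
    for assay, _ in truth.undetermined:
        if assay not in known_assays:
            raise ConfigurationError(
                f"undetermined fraction references unknown assay {assay!r}")


# ---------------------------------------------------------------------------
# generators


def generate_mrna_arrays(design: CohortDesign, truth: PlantedTruth) -> ExpressionMatrix:
    """Two-channel-style array matrix: log10 ratios of tumour vs pooled
    reference.  Non-planted genes ~ Normal(0, sigma_lr^2); planted genes are
    shifted by +effect in their up-subtype (the pooled reference is emulated
    as the cross-subtype mean, so effects are expressed directly as ratio
    shifts)."""
    _check_truth_features(design, truth)
    rng = np.random.default_rng([design.seed, 101])
    genes = gene_universe(design)
    frame = _sample_frame(design)
    sample_ids = [p + "-T" for p in frame["patient_id"]]
    subtype = frame["subtype"].to_numpy()
    values = rng.normal(0.0, truth.noise_sd_logratio,
                        size=(len(genes), len(sample_ids)))
    gene_index = {g: i for i, g in enumerate(genes)}
    for gene, sub, eff in truth.de_genes:
        mask = subtype == sub
        values[gene_index[gene], mask] += eff
    metadata = pd.DataFrame(
        {
            "subtype": subtype,
            "cohort": design.cohort,
            "tissue": "tumor",
            "patient_id": frame["patient_id"].to_numpy(),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    vdf = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                       columns=sample_ids)
    return ExpressionMatrix(values=vdf, metadata=metadata)


def generate_ct_tables(design: CohortDesign, truth: PlantedTruth,
                       mrna_assays: list[str] | None = None) -> tuple[CtTable, CtTable]:
    """Generate qPCR Ct tables for miRNAs and mRNAs.

    Returns ``(mirna_ct, mrna_ct)``.  miRNA assays cover the whole miRNA
    universe plus the RNU48 reference; mRNA assays default to the genes named
    in the truth (planted + decoy targets) plus the three housekeeping
    candidates, emulating a targeted validation panel.  With
    ``design.paired_normals`` every patient contributes tumour and
    adjacent-normal tissue; subtype effects apply to tumour tissue only.
    """
    _check_truth_features(design, truth)
    rng = np.random.default_rng([design.seed, 202])
    frame = _sample_frame(design)
    tissues = ["tumor", "normal"] if design.paired_normals else ["tumor"]
    n_pat = len(frame)
    pair_parents = truth.pair_parents()

    if mrna_assays is None:
        named = [g for g, _, _ in truth.de_genes]
        named += [g for _, g in truth.decoy_pairs if g not in named]
        mrna_assays = named
    for g in mrna_assays:
        if g in _HOUSEKEEPING:
            raise ConfigurationError(
                f"housekeeping assay {g!r} is added automatically")

    mirna_assays = mirna_universe(design)
    mirna_dir = truth.mirna_directions()
    mirna_effect = {m: e for m, _, e in truth.de_mirnas}
    gene_dir = truth.gene_directions()
    gene_effect = {g: e for g, _, e in truth.de_genes}
    subtype = frame["subtype"].to_numpy()
    undet = dict(truth.undetermined)

    # latent miRNA expression deviations per (assay, tissue, patient), shared
    # between the miRNA's own Ct and any coupled gene's Ct
    latent: dict[tuple[str, str], np.ndarray] = {}
    for m in mirna_assays:
        for tis in tissues:
            e = rng.normal(0.0, truth.mirna_biological_sd, size=n_pat)
            if tis == "tumor" and m in mirna_dir:
                e = e + mirna_effect[m] * (subtype == mirna_dir[m])
            latent[(m, tis)] = e

    base_mirna = {m: v for m, v in zip(
        mirna_assays, rng.uniform(22.0, 30.0, size=len(mirna_assays)))}
    base_gene = {g: v for g, v in zip(
        mrna_assays, rng.uniform(20.0, 28.0, size=len(mrna_assays)))}

    rows_mirna = _emit_assays(
        design, frame, tissues, rng, undet,
        assays=mirna_assays + [MIRNA_REFERENCE],
        level_fn=lambda a, tis: (
            _housekeeping_level(a, rng, n_pat, truth.noise_sd_ct)
            if a == MIRNA_REFERENCE
            else base_mirna[a] - latent[(a, tis)]
        ),
        noise_sd=truth.noise_sd_ct,
    )
    gene_bio_sd = GENE_NOISE_RATIO * truth.noise_sd_ct

    def gene_level(g: str, tis: str) -> np.ndarray:
        if g in _HOUSEKEEPING:
            return _housekeeping_level(g, rng, n_pat, truth.noise_sd_ct)
        level = np.full(n_pat, base_gene[g], dtype=float)
        if g in pair_parents:
            for mirna, slope in pair_parents[g]:
                level = level + slope * latent[(mirna, tis)]
        elif tis == "tumor" and g in gene_dir:
            level = level - gene_effect[g] * LOG2_10 * (subtype == gene_dir[g])
        level = level + rng.normal(0.0, gene_bio_sd, size=n_pat)
        return level

    rows_mrna = _emit_assays(
        design, frame, tissues, rng, undet,
        assays=list(mrna_assays) + list(MRNA_REFERENCES),
        level_fn=gene_level,
        noise_sd=truth.noise_sd_ct,
    )
    return CtTable(data=rows_mirna), CtTable(data=rows_mrna)


def _housekeeping_level(assay: str, rng: np.random.Generator,
                        n_pat: int, noise_sd_ct: float) -> np.ndarray:
    base, sd_ratio = _HOUSEKEEPING[assay]
    return base + rng.normal(0.0, sd_ratio * noise_sd_ct, size=n_pat)


def _emit_assays(design, frame, tissues, rng, undet, assays, level_fn,
                 noise_sd) -> pd.DataFrame:
    """Emit replicate-level Ct rows; undetermined samples lose every
    replicate of the affected assay (count = round(fraction * n samples),
    membership drawn from the generator stream)."""
    n_pat = len(frame)
    chunks = []
    for assay in assays:
        for tis in tissues:
            level = level_fn(assay, tis)
            reps = np.arange(1, design.n_replicates + 1)
            ct = (level[:, None]
                  + rng.normal(0.0, noise_sd, size=(n_pat, len(reps))))
            ct = np.clip(ct, 1.0, 45.0)
            mask = np.zeros(n_pat, dtype=bool)
            if assay in undet and undet[assay] > 0:
                k = int(round(undet[assay] * n_pat))
                mask[rng.choice(n_pat, size=k, replace=False)] = True
            df = pd.DataFrame({
                "assay": assay,
                "patient_id": np.repeat(frame["patient_id"].to_numpy(), len(reps)),
                "tissue": tis,
                "replicate": np.tile(reps, n_pat),
                "ct": ct.ravel(),
            })
            df.loc[np.repeat(mask, len(reps)), "ct"] = np.nan
            chunks.append(df)
    return pd.concat(chunks, ignore_index=True)


# ---------------------------------------------------------------------------
# truth serialization (JSON round-trips floats exactly)


def write_truth(truth: PlantedTruth, path) -> None:
    payload = asdict(truth)
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def _as_tuples(items) -> tuple:
    return tuple(tuple(x) for x in items)


def read_truth(path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return PlantedTruth(
        de_genes=_as_tuples(payload["de_genes"]),
        de_mirnas=_as_tuples(payload["de_mirnas"]),
        true_pairs=_as_tuples(payload["true_pairs"]),
        decoy_pairs=_as_tuples(payload["decoy_pairs"]),
        noise_sd_logratio=payload["noise_sd_logratio"],
        noise_sd_ct=payload["noise_sd_ct"],
        mirna_biological_sd=payload["mirna_biological_sd"],
        undetermined=_as_tuples(payload["undetermined"]),
    )
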