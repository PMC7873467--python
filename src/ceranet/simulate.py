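"""Synthetic paired expression and interaction data with planted truth.

The generator emulates the study design every downstream stage expects:
eight patients each contributing one ectopic (EC) and one eutopic (EU)
sample, profiled for mRNAs, lncRNAs and miRNAs on a log2 scale, plus
bipartite miRNA-target interaction tables.  Ground truth is planted so
recovery can be scored:

* a fraction ``frac_de`` of features in every class is differentially
  expressed, with a per-feature random sign on a ``log2fc_planted``
  shift so both Up and Down classes are exercised;
* every planted lncRNA owns a dedicated miRNA repertoire
  (``shared_mirna_count + lncrna_repertoire_extra`` planted-DE miRNAs,
  disjoint between lncRNAs, the way a sponge lncRNA has one fixed
  partner set); each of its ``n_planted_cerna_pairs`` competing mRNAs
  is wired to a random ``shared_mirna_count``-sized subset of that
  repertoire, so the pair's shared count stays decisively above the
  background edge density even for hubs with many competing mRNAs;
* ``n_hub_lncrna`` hub lncRNAs each absorb several planted pairs, so
  the network has a few high-degree nodes over many degree-1 ones;
* ``n_disease_lncrna`` disease-proximal lncRNAs compete (via dedicated
  shared miRNAs) with every designated seed gene, i.e. they sit two
  hops from the seeds through the competing edges a restart walk
  propagates over.

Expression model: each feature's baseline mean is drawn uniformly on a
wide log2 range, i.i.d. Gaussian noise is added per sample, and the
planted shift is applied to EC samples only.  This is deliberately a
log-scale location model, not a read-count simulation: library size,
count overdispersion and normalization artifacts are out of scope.

``frac_de = 0`` yields pure null data: no planted structure of any kind
(pairs, hubs and disease lncRNAs need DE members), only background
interaction edges.

Everything is deterministic for a fixed ``rng_seed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    InteractionSet,
    PairedExpressionSet,
    read_expression,
    read_interactions,
    read_seed_list,
)

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticDataset",
           "generate_dataset", "write_fixture", "read_fixture"]

RNA_CLASSES = ("mrna", "lncrna", "mirna")


class SizingError(ValueError):
    """The requested planted structure cannot fit in the feature budget."""


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults mirror the emulated study design
    (8 paired patients, 2-fold planted effects) at desk-scale feature
    counts."""

    n_patients: int = 8
    n_mrna: int = 300
    n_lncrna: int = 60
    n_mirna: int = 350
    frac_de: float = 0.3
    log2fc_planted: float = 2.0
    noise_sd: float = 0.3
    n_planted_cerna_pairs: int = 10
    shared_mirna_count: int = 5
    n_hub_lncrna: int = 1
    n_disease_lncrna: int = 1
    seed_gene_count: int = 4
    background_edges_per_mirna: int = 3
    hub_pair_fraction: float = 0.6
    lncrna_repertoire_extra: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_mrna", "n_lncrna", "n_mirna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.shared_mirna_count > self.n_mirna:
            raise ValueError("shared_mirna_count cannot exceed n_mirna")
        for name in (
            "n_planted_cerna_pairs",
            "n_hub_lncrna",
            "n_disease_lncrna",
            "seed_gene_count",
            "background_edges_per_mirna",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self._check_budget()

    def _check_budget(self) -> None:
        if self.frac_de == 0:
            return  # null data: nothing structural is planted
        n_de_mirna = round(self.frac_de * self.n_mirna)
        n_de_mrna = round(self.frac_de * self.n_mrna)
        n_de_lncrna = round(self.frac_de * self.n_lncrna)
        n_hub_pairs = self._hub_pair_count() * max(self.n_hub_lncrna, 1)
        need_lnc = (
            self.n_hub_lncrna
            + self.n_disease_lncrna
            + max(0, self.n_planted_cerna_pairs - n_hub_pairs)
        )
        repertoire = self.shared_mirna_count + self.lncrna_repertoire_extra
        need_mirna = need_lnc * repertoire
        if need_mirna > n_de_mirna:
            raise SizingError(
                f"planted lncRNAs need {need_mirna} dedicated DE miRNAs "
                f"({need_lnc} lncRNAs x {repertoire}-miRNA repertoires) but only "
                f"{n_de_mirna} are available (frac_de * n_mirna); reduce pairs "
                f"or shared_mirna_count, or raise n_mirna/frac_de"
            )
        if need_lnc > n_de_lncrna:
            raise SizingError(
                f"planted structure needs {need_lnc} DE lncRNAs but only "
                f"{n_de_lncrna} are available"
            )
        need_mrna = self.n_planted_cerna_pairs + self.seed_gene_count
        if need_mrna > n_de_mrna:
            raise SizingError(
                f"planted structure needs {need_mrna} DE mRNAs but only "
                f"{n_de_mrna} are available"
            )

    def _hub_pair_count(self) -> int:
        """Planted pairs absorbed by each hub lncRNA."""
        if self.n_hub_lncrna == 0 or self.n_planted_cerna_pairs == 0:
            return 0
        return max(
            1,
            int(round(self.hub_pair_fraction * self.n_planted_cerna_pairs))
            // self.n_hub_lncrna,
        )


@dataclass
class GroundTruth:
    """Planted entities, keyed by the feature names of the dataset."""

    planted_de: dict[str, dict[str, str]]  # class -> feature -> Up/Down
    planted_pairs: list[tuple[str, str]]  # (lncrna, mrna)
    pair_mirnas: dict[str, list[str]]  # "lnc|mrna" -> dedicated shared miRNAs
    hub_lncrnas: list[str]
    disease_lncrnas: list[str]
    seed_genes: list[str]


@dataclass
class SyntheticDataset:
    expression: PairedExpressionSet
    interactions: InteractionSet
    truth: GroundTruth
    config: SyntheticConfig


def _feature_names(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one synthetic dataset with planted ground truth."""
    rng = np.random.default_rng(config.rng_seed)
    names = {
        "mrna": _feature_names("MRNA", config.n_mrna),
        "lncrna": _feature_names("LNC", config.n_lncrna),
        "mirna": _feature_names("MIR", config.n_mirna),
    }

    # --- choose planted-DE features and their directions ----------------
    planted_de: dict[str, dict[str, str]] = {}
    for cls in RNA_CLASSES:
        n_de = round(config.frac_de * len(names[cls]))
        chosen = [str(f) for f in rng.choice(names[cls], size=n_de, replace=False)]
        signs = rng.choice([1, -1], size=n_de)
        planted_de[cls] = {
            f: ("Up" if s > 0 else "Down") for f, s in zip(sorted(chosen), signs)
        }

    # --- allocate planted network structure from the DE pools ------------
    pairs: list[tuple[str, str]] = []
    pair_mirnas: dict[str, list[str]] = {}
    hubs: list[str] = []
    disease: list[str] = []
    seed_genes: list[str] = []
    planted_edges: list[tuple[str, str, str]] = []

    if config.frac_de > 0:
        de_mrna = sorted(planted_de["mrna"])
        de_lnc = sorted(planted_de["lncrna"])
        de_mir = sorted(planted_de["mirna"])
        mir_pool = [str(x) for x in rng.permutation(de_mir)]
        mrna_pool = [str(x) for x in rng.permutation(de_mrna)]
        lnc_pool = [str(x) for x in rng.permutation(de_lnc)]

        hubs = [lnc_pool.pop() for _ in range(config.n_hub_lncrna)]
        disease = [lnc_pool.pop() for _ in range(config.n_disease_lncrna)]
        seed_genes = [mrna_pool.pop() for _ in range(config.seed_gene_count)]

        hub_pairs_each = config._hub_pair_count()
        lnc_for_pair: list[str] = []
        for hub in hubs:
            lnc_for_pair.extend([hub] * hub_pairs_each)
        while len(lnc_for_pair) < config.n_planted_cerna_pairs:
            lnc_for_pair.append(lnc_pool.pop())
        lnc_for_pair = lnc_for_pair[: config.n_planted_cerna_pairs]

        repertoires: dict[str, list[str]] = {}

        def plant_pair(lnc: str, mrna: str) -> None:
            if lnc not in repertoires:
                size = config.shared_mirna_count + config.lncrna_repertoire_extra
                repertoires[lnc] = [mir_pool.pop() for _ in range(size)]
                for mir in repertoires[lnc]:
                    planted_edges.append((mir, lnc, "lncRNA"))
            shared = sorted(
                str(m)
                for m in rng.choice(
                    repertoires[lnc], size=config.shared_mirna_count, replace=False
                )
            )
            pairs.append((lnc, mrna))
            pair_mirnas[f"{lnc}|{mrna}"] = shared
            for mir in shared:
                planted_edges.append((mir, mrna, "mRNA"))

        for lnc in lnc_for_pair:
            plant_pair(lnc, mrna_pool.pop())
        for lnc in disease:
            for gene in seed_genes:
                plant_pair(lnc, gene)

    # --- background interaction edges ------------------------------------
    all_targets = [(m, "mRNA") for m in names["mrna"]] + [
        (l, "lncRNA") for l in names["lncrna"]
    ]
    bg_edges: list[tuple[str, str, str]] = []
    if config.background_edges_per_mirna > 0:
        for mir in names["mirna"]:
            picks = rng.choice(
                len(all_targets), size=config.background_edges_per_mirna, replace=False
            )
            for i in picks:
                tgt, cls = all_targets[i]
                bg_edges.append((mir, tgt, cls))

    edges = pd.DataFrame(
        planted_edges + bg_edges, columns=["mirna_id", "target_id", "target_class"]
    )
    interactions = InteractionSet(edges)

    # --- expression matrices ---------------------------------------------
    patients = [f"P{i}" for i in range(1, config.n_patients + 1)]
    sheet = pd.DataFrame(
        [
            {"sample_id": f"{p}_{cond}", "patient_id": p, "condition": cond}
            for p in patients
            for cond in ("EC", "EU")
        ]
    )
    matrices: dict[str, pd.DataFrame] = {}
    for cls in RNA_CLASSES:
        feats = names[cls]
        n_feat, n_pat = len(feats), config.n_patients
        baseline = rng.uniform(4.0, 12.0, size=n_feat)
        shift = np.zeros(n_feat)
        for i, f in enumerate(feats):
            direction = planted_de[cls].get(f)
            if direction is not None:
                shift[i] = config.log2fc_planted if direction == "Up" else -config.log2fc_planted
        eu = baseline[:, None] + rng.normal(0, config.noise_sd, size=(n_feat, n_pat))
        ec = (
            baseline[:, None]
            + shift[:, None]
            + rng.normal(0, config.noise_sd, size=(n_feat, n_pat))
        )
        cols, data = [], []
        for j, p in enumerate(patients):
            cols += [f"{p}_EC", f"{p}_EU"]
            data += [ec[:, j], eu[:, j]]
        mat = pd.DataFrame(
            np.column_stack(data), index=pd.Index(feats, name="feature_id"), columns=cols
        )
        matrices[cls] = mat

    expression = PairedExpressionSet(matrices=matrices, sample_sheet=sheet)
    truth = GroundTruth(
        planted_de=planted_de,
        planted_pairs=pairs,
        pair_mirnas=pair_mirnas,
        hub_lncrnas=hubs,
        disease_lncrnas=disease,
        seed_genes=seed_genes,
    )
    return SyntheticDataset(
        expression=expression, interactions=interactions, truth=truth, config=config
    )


# ---------------------------------------------------------------------------
# fixture round-trip
# ---------------------------------------------------------------------------

_MATRIX_FILES = {"mrna": "mrna.tsv", "lncrna": "lncrna.tsv", "mirna": "mirna.tsv"}


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write a dataset as the pipeline's on-disk input formats.

    Emits one expression TSV per class, a sample sheet, the interaction
    table, the seed-gene list and a JSON truth manifest; all files
    round-trip losslessly through the :mod:`ceranet.io` readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    try:
        for cls, fname in _MATRIX_FILES.items():
            if cls in dataset.expression.matrices:
                path = directory / fname
                dataset.expression.matrices[cls].to_csv(path, sep="\t", float_format="%.10g")
                out[cls] = path
        out["samples"] = directory / "samples.tsv"
        dataset.expression.sample_sheet.to_csv(out["samples"], sep="\t", index=False)
        out["interactions"] = directory / "interactions.tsv"
        dataset.interactions.edges.to_csv(out["interactions"], sep="\t", index=False)
        out["seeds"] = directory / "seeds.txt"
        out["seeds"].write_text("".join(f"{g}\n" for g in dataset.truth.seed_genes))
        out["truth"] = directory / "truth.json"
        manifest = {
            "planted_de": dataset.truth.planted_de,
            "planted_pairs": [list(p) for p in dataset.truth.planted_pairs],
            "pair_mirnas": dataset.truth.pair_mirnas,
            "hub_lncrnas": dataset.truth.hub_lncrnas,
            "disease_lncrnas": dataset.truth.disease_lncrnas,
            "seed_genes": dataset.truth.seed_genes,
            "config": asdict(dataset.config),
        }
        out["truth"].write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
    return out


def read_fixture(directory: str | Path) -> SyntheticDataset:
    """Read back a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    manifest = json.loads((directory / "truth.json").read_text())
    config = SyntheticConfig(**manifest["config"])
    matrices = {}
    sheet = None
    for cls, fname in _MATRIX_FILES.items():
        path = directory / fname
        if path.exists():
            matrices[cls], sheet = read_expression(path, directory / "samples.tsv")
    expression = PairedExpressionSet(matrices=matrices, sample_sheet=sheet)
    interactions = read_interactions(directory / "interactions.tsv")
    truth = GroundTruth(
        planted_de=manifest["planted_de"],
        planted_pairs=[tuple(p) for p in manifest["planted_pairs"]],
        pair_mirnas=manifest["pair_mirnas"],
        hub_lncrnas=manifest["hub_lncrnas"],
        disease_lncrnas=manifest["disease_lncrnas"],
        seed_genes=read_seed_list(directory / "seeds.txt"),
    )
    return SyntheticDataset(
        expression=expression, interactions=interactions, truth=truth, config=config
    )
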