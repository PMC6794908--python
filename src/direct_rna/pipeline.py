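"""End-to-end orchestration: train template RBM → Gibbs sample → contact
weight → mfDCA → DIRECT reweighting → ranked contacts → evaluation.

Two entry points: :func:`run_direct` works from files (what the CLI
wraps); :func:`predict_instance` runs the same stages on an in-memory
synthetic instance and is what the test suite and the reproduction
script use.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import contact_maps as cmaps
from . import dca, evaluation, io_formats, rbm, scoring, synthetic

logger = logging.getLogger("direct_rna")


@dataclass
class RunConfig:
    """Every knob of a full run, with the method's published defaults."""

    training_maps_dir: str | None = None
    msa_path: str | None = None
    native_map_path: str | None = None
    ss_path: str | None = None
    exclusion_ids: tuple = ()
    template_size: int = 100
    n_hidden: int = 100
    learning_rate: float = 0.1
    epochs: int = 10_000
    cd_k: int = 1
    n_total: int = 10_000
    n_keep: int = 5_000
    cutoff: float = 8.0
    min_separation: int = 4
    exponent: int = 2
    pseudocount: float = 0.5
    reweight_threshold: float = 0.8
    max_gap_fraction: float = 0.5
    top_n: int = 100
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def exclude_homologs(training_ids, target_id, exclusion_ids):
    """Drop user-listed homologs of the target from the training set.

    Homology detection itself is delegated to the user; with no
    exclusion list the input passes through with a leakage warning.
    """
    training_ids = list(training_ids)
    if not exclusion_ids:
        warnings.warn("possible train/test leakage: no exclusion list supplied")
        return training_ids
    excluded = set(exclusion_ids) | {target_id}
    kept = [t for t in training_ids if t not in excluded]
    logger.info("excluded %d of %d training maps", len(training_ids) - len(kept), len(training_ids))
    return kept


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def learn_template(
    training_distances,
    template_size: int = 100,
    n_hidden: int = 100,
    learning_rate: float = 0.1,
    epochs: int = 10_000,
    cd_k: int = 1,
    n_total: int = 10_000,
    n_keep: int = 5_000,
    cutoff: float = 8.0,
    seed: int = 0,
) -> rbm.TemplateWeight:
    """Train the RBM on resized training maps and extract the contact
    frequency template from Gibbs samples."""
    vectors = synthetic.training_vectors(training_distances, template_size, cutoff)
    model = rbm.train_cd(
        vectors,
        n_hidden=n_hidden,
        learning_rate=learning_rate,
        epochs=epochs,
        cd_k=cd_k,
        seed=seed,
    )
    # Start the chain at a training example: the learned density is sharply
    # concentrated, and a random state mixes into it far too slowly.
    samples = rbm.gibbs_sample(
        model, n_total=n_total, n_keep=n_keep, seed=seed + 1, init=vectors[0]
    )
    return rbm.contact_weight(samples, template_size)


def predict_instance(
    instance: synthetic.SyntheticInstance,
    epochs: int = 2_000,
    n_hidden: int = 100,
    template_size: int = 100,
    n_total: int = 10_000,
    n_keep: int = 5_000,
    top_n: int = 30,
    exponent: int = 2,
    min_separation: int = 4,
    seed: int = 0,
    family_distances=None,
) -> dict:
    """Run the full method on a synthetic instance.

    Returns both the coevolution-only (DI) and template-reweighted
    (DIRECT) rankings with their top-n PPVs against the native tertiary
    contacts.  ``family_distances`` overrides the instance's own family
    (used for mismatched-template controls).
    """
    fam = instance.family_distances if family_distances is None else family_distances
    template = learn_template(
        fam,
        template_size=template_size,
        n_hidden=n_hidden,
        epochs=epochs,
        n_total=n_total,
        n_keep=n_keep,
        seed=seed,
    )
    di = dca.di_from_msa(instance.msa)
    w_proj = scoring.project_weight(template, instance.length)
    direct = scoring.direct_reweight(di, w_proj, exponent=exponent)

    ranked_di = scoring.rank_contacts(di, min_separation, top_n, scoring.SCHEME_DI)
    ranked_direct = scoring.rank_contacts(direct, min_separation, top_n, scoring.SCHEME_DIRECT)
    native = cmaps.ContactMap(instance.native_map.values, min_separation=min_separation)
    return {
        "template": template,
        "w_projected": w_proj,
        "di_matrix": di,
        "ranked_di": ranked_di,
        "ranked_direct": ranked_direct,
        "ppv_di": evaluation.ppv(ranked_di, native),
        "ppv_direct": evaluation.ppv(ranked_direct, native),
    }


def run_direct(config: RunConfig):
    """File-based full run (the Fig-style a→b→c workflow).

    Returns (ScoredContacts, EvaluationReport | None, manifest dict).
    """
    manifest = {"config": asdict(config), "inputs": {}, "versions": _versions()}

    maps_dir = Path(config.training_maps_dir)
    map_paths = sorted(maps_dir.glob("*.tsv"))
    if not map_paths:
        raise FileNotFoundError(f"no training maps in {maps_dir}")
    kept_ids = exclude_homologs(
        [p.stem for p in map_paths], target_id="target", exclusion_ids=config.exclusion_ids
    )
    map_paths = [p for p in map_paths if p.stem in set(kept_ids)]
    for p in map_paths:
        manifest["inputs"][p.name] = _sha256(p)
    distances = [io_formats.read_dense(p.read_text()) for p in map_paths]

    template = learn_template(
        distances,
        template_size=config.template_size,
        n_hidden=config.n_hidden,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        cd_k=config.cd_k,
        n_total=config.n_total,
        n_keep=config.n_keep,
        cutoff=config.cutoff,
        seed=config.seed,
    )

    msa_path = Path(config.msa_path)
    manifest["inputs"][msa_path.name] = _sha256(msa_path)
    msa = io_formats.read_msa(msa_path.read_text())
    di = dca.di_from_msa(
        msa,
        max_gap_fraction=config.max_gap_fraction,
        identity_threshold=config.reweight_threshold,
        pseudocount_weight=config.pseudocount,
    )
    w_proj = scoring.project_weight(template, msa.length)
    direct = scoring.direct_reweight(di, w_proj, exponent=config.exponent)
    ranked = scoring.rank_contacts(
        direct, config.min_separation, config.top_n, scoring.SCHEME_DIRECT
    )

    report = None
    if config.native_map_path:
        native_path = Path(config.native_map_path)
        manifest["inputs"][native_path.name] = _sha256(native_path)
        native_vals = io_formats.read_dense(native_path.read_text())
        if native_vals.max() > 1:  # distances, not a binary map
            native = cmaps.contact_map(native_vals, config.cutoff, config.min_separation)
        else:
            native = cmaps.ContactMap(native_vals.astype(np.uint8), config.cutoff, config.min_separation)
        ss = None
        if config.ss_path:
            ss = io_formats.read_dotbracket(Path(config.ss_path).read_text())
        report = evaluation.breakdown(
            ranked, native, ss=ss, n=config.top_n, categories=ss is not None
        )
    return ranked, report, manifest


def _versions() -> dict:
    import Bio
    import scipy

    return {"numpy": np.__version__, "scipy": scipy.__version__, "biopython": Bio.__version__}
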