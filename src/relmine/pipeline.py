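"""End-to-end orchestration: NER -> EL -> RE -> ND over a corpus.

Stages run sequentially, each consuming the previous stage's output; a
gold-entities mode skips NER and EL so relation extraction and novelty
detection run on gold annotations (the usual "subtask 1" evaluation setting).
Stage outputs are fresh corpora (inputs are never mutated) and a run manifest
records seeds and configuration for reproducibility.

:func:`train_pipeline` trains every stage on a generated synthetic world at
desk scale (tiny encoder, scaled-down epochs/learning rates suited to
training from random initialisation); the full-scale defaults on each
stage's config dataclass remain untouched for real corpora.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field

from .corpus import Corpus
from .encoder import TinyEncoder, TinyEncoderSpec
from .linking import (ResCNN, ResCNNConfig, augment_index_with_training,
                      build_synonym_index, fit_rescnn, link_corpus)
from .ner import ALL_TAG, TokenNERConfig, fit_token_ner, merge_corpora, \
    postprocess_mentions, predict_mentions
from .novelty import NDConfig, fit_nd, predict_novelty
from .relations import (AdversarialConfig, REConfig, fit_re,
                        generate_candidate_pairs, predict_doc_relations,
                        NO_RELATION)
from .synthetic import SyntheticWorld, make_tiny_encoder

logger = logging.getLogger(__name__)

__all__ = ["PipelineModels", "PipelineConfig", "run_pipeline", "train_pipeline",
           "save_models", "load_models", "desk_scale_configs"]


@dataclass
class PipelineModels:
    ner_model: object = None
    indexes: dict = field(default_factory=dict)  # etype -> SynonymIndex
    external: Corpus | None = None
    re_model: object = None
    nd_model: object = None


@dataclass
class PipelineConfig:
    seed: int = 0
    gold_entities: bool = False  # skip NER + EL, keep gold mentions/ids
    max_len: int = 512


def run_pipeline(corpus: Corpus, models: PipelineModels,
                 cfg: PipelineConfig | None = None) -> tuple[Corpus, dict]:
    """Run the staged pipeline; returns (predicted corpus, run manifest)."""
    cfg = cfg or PipelineConfig()
    if models.re_model is None or models.nd_model is None:
        raise ValueError("RE and ND models are required before any stage runs")
    if not cfg.gold_entities and (models.ner_model is None):
        raise ValueError("NER model required unless gold_entities is set")

    stage_outputs = {}
    # --- NER ---------------------------------------------------------
    current = corpus.copy()
    if not cfg.gold_entities:
        for doc in current:
            mentions = predict_mentions(models.ner_model, doc, ALL_TAG)
            doc.mentions = postprocess_mentions(doc, mentions)
            doc.relations = []
        stage_outputs["ner"] = current.copy()
        # --- EL ------------------------------------------------------
        external = models.external if models.external is not None else Corpus([])
        current = link_corpus(current, external, models.indexes)
        stage_outputs["el"] = current.copy()
    else:
        for doc in current:
            doc.relations = []
        stage_outputs["gold_entities"] = current.copy()

    # --- RE ----------------------------------------------------------
    for doc in current:
        doc.relations = predict_doc_relations(models.re_model, doc,
                                              max_len=cfg.max_len)
    stage_outputs["re"] = current.copy()

    # --- ND ----------------------------------------------------------
    for doc in current:
        doc.relations = predict_novelty(models.nd_model, doc, doc.relations,
                                        max_len=cfg.max_len)

    manifest = {
        "seed": cfg.seed,
        "gold_entities": cfg.gold_entities,
        "stages": ["ner", "el", "re", "nd"] if not cfg.gold_entities else ["re", "nd"],
        "n_documents": len(corpus),
    }
    return current, manifest


# ----------------------------------------------------------------------
# desk-scale training
# ----------------------------------------------------------------------

def desk_scale_configs() -> dict:
    """Stage configs for training the tiny encoder from random init."""
    return {
        "encoder": TinyEncoderSpec(dim=32, n_layers=2, ffn_dim=64),
        "ner": TokenNERConfig(learning_rate=2e-3, batch_size=16, epochs=10),
        "rescnn": ResCNNConfig(pooling="max", learning_rate=1e-3,
                               n_encoder_blocks=2, feature_size=64,
                               dropout=0.1, n_filters=32, epochs=30,
                               eval_every=5),
        "re": REConfig(epochs=10, learning_rate=3e-3, batch_size=8),
        "adv": AdversarialConfig(n_steps=3, step_size=0.3, radius=1.0),
        "nd": NDConfig(epochs=8, learning_rate=3e-3, batch_size=8),
    }


def train_pipeline(world: SyntheticWorld, seed: int = 0,
                   configs: dict | None = None,
                   with_adversarial: bool = True) -> PipelineModels:
    """Train every stage on the world's training corpus."""
    cfgs = desk_scale_configs()
    if configs:
        cfgs.update(configs)

    # each stage fine-tunes its own copy of the encoder
    def fresh_encoder(offset: int) -> TinyEncoder:
        spec = cfgs["encoder"]
        return make_tiny_encoder(world, TinyEncoderSpec(
            dim=spec.dim, n_layers=spec.n_layers, ffn_dim=spec.ffn_dim,
            seed=seed + offset))

    logger.info("training token NER ...")
    instances, label_space = merge_corpora([(world.train, ALL_TAG)], cfgs["ner"])
    ner_model = fit_token_ner(instances, fresh_encoder(1), cfgs["ner"],
                              seed=seed, label_space=label_space)

    logger.info("training ResCNN linkers ...")
    indexes = {}
    for etype in ("Disease", "Chemical"):
        rows = [(ident, syn) for ident, syn in world.vocab_rows
                if world.entity_types.get(ident) == etype]
        rescnn = ResCNN(fresh_encoder(2), cfgs["rescnn"], seed=seed)
        index = build_synonym_index(rows, rescnn)
        pairs = sorted({(m.surface, m.identifiers[0]) for doc in world.train
                        for m in doc.mentions
                        if m.etype == etype and len(m.identifiers) == 1})
        fit_rescnn(pairs, index, cfgs["rescnn"], seed=seed)
        index = augment_index_with_training(index, world.train)
        indexes[etype] = index

    logger.info("training RE ...")
    doc_instances = [(doc, generate_candidate_pairs(doc, world.allowed_pairs))
                     for doc in world.train]
    re_model = fit_re(doc_instances, fresh_encoder(3), cfgs["re"],
                      adv=cfgs["adv"] if with_adversarial else None,
                      seed=seed, allowed=world.allowed_pairs)

    logger.info("training ND ...")
    nd_doc_instances = [
        (doc, [inst for inst in instances_ if inst.label != NO_RELATION])
        for doc, instances_ in doc_instances]
    nd_model = fit_nd(nd_doc_instances, fresh_encoder(4), cfgs["nd"], seed=seed)

    return PipelineModels(ner_model=ner_model, indexes=indexes,
                          external=world.external_dev, re_model=re_model,
                          nd_model=nd_model)


def save_models(models: PipelineModels, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(models, fh)


def load_models(path) -> PipelineModels:
    with open(path, "rb") as fh:
        return pickle.load(fh)
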