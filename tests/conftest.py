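from datetime import datetime

import pytest

from lsspanel.corpus import Document, build_dtm
from lsspanel.lss import LSSConfig, fit_lss, score_corpus
from lsspanel.synthetic import SyntheticConfig, generate_corpus


def make_doc(doc_id, tokens, user="u0", ts="2020-01-15", **kw):
    return Document(doc_id=doc_id, user_id=user, timestamp=datetime.fromisoformat(ts),
                    tokens=list(tokens), **kw)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study: 40 users, 150-term vocabulary, ~8k documents."""
    return SyntheticConfig(random_seed=7, n_users=40, vocab_size=150)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_corpus(small_config)


@pytest.fixture(scope="session")
def small_scored(small_study):
    """Fitted scaler + scored-document table for the small synthetic study."""
    data = small_study
    dtm = build_dtm(data.documents, min_term_count=5)
    model = fit_lss(dtm, data.truth.seed_lexicon(),
                    LSSConfig(embedding_dim=30, random_seed=7))
    meta = data.latent[["doc_id", "user_id"]].assign(timestamp=data.latent["date"])
    scores = score_corpus(model, dtm, doc_meta=meta)
    return model, scores
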