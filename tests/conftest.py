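import pytest

from nanoct import ClassifierSpec, GeneratorConfig, corpus_to_bags, generate


def record_xml(nct_id="NCT00000001", fields=(), extra_attr=False):
    """Build a minimal study-record XML string."""
    attr = ' schema_version="1"' if extra_attr else ""
    body = "".join(
        f"<{tag}><textblock>{text}</textblock></{tag}>"
        if tag in ("brief_summary", "detailed_description")
        else f"<{tag}>{text}</{tag}>"
        for tag, text in fields
    )
    return (
        f'<clinical_study{attr}><id_info><nct_id>{nct_id}</nct_id></id_info>'
        f"{body}</clinical_study>"
    )


@pytest.fixture(scope="session")
def l1_idf_spec():
    return ClassifierSpec(family="l1_logreg", seed=0)


@pytest.fixture(scope="session")
def signal_synth():
    """Balanced 200-document corpus with the stated injected-signal
    condition: 20 class terms per class at 5% per-token injection."""
    sc = generate(GeneratorConfig(n_per_class=100, seed=1))
    return sc, corpus_to_bags(sc.corpus.texts)


@pytest.fixture(scope="session")
def null_synth():
    """Null construction: equal injection and cross rates, so the two
    class-conditional token distributions are identical in expectation."""
    sc = generate(
        GeneratorConfig(n_per_class=100, injection_rate=0.02, cross_rate=0.02,
                        seed=1)
    )
    return sc, corpus_to_bags(sc.corpus.texts)


@pytest.fixture(scope="session")
def weak_synth():
    """Weak-signal corpus (0.5% injection) whose learning curve is still
    rising — informative for training-size effects, unlike the saturated
    strong-signal condition."""
    sc = generate(
        GeneratorConfig(n_per_class=100, injection_rate=0.005, seed=1)
    )
    return sc, corpus_to_bags(sc.corpus.texts)
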