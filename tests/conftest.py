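import json
from pathlib import Path

import pytest

from cdmo import fixtures, rule_engine

RULES_FILE = Path(rule_engine.__file__).parent / "rules" / "diabetes_core.rules"


@pytest.fixture(scope="session")
def micro_onto():
    return fixtures.make_micro_ontology(7)


@pytest.fixture(scope="session")
def clinical_rules():
    return rule_engine.load_rules(RULES_FILE)


@pytest.fixture(scope="session")
def target_bundle():
    """(target graph, planted mapping table, planted ground-truth edges)."""
    return fixtures.make_target_ontology(7)


@pytest.fixture(scope="session")
def corpus_bundle():
    return fixtures.make_corpus(7)


@pytest.fixture(scope="session")
def patient_bundle(micro_onto, tmp_path_factory):
    """(knowledge base, per-patient ground-truth closure)."""
    abox, truth = fixtures.make_patients(7)
    path = tmp_path_factory.mktemp("abox") / "patients.json"
    path.write_text(json.dumps(abox, ensure_ascii=False), encoding="utf-8")
    kb = rule_engine.load_abox(path, micro_onto)
    return kb, truth
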