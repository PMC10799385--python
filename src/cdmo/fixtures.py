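"""Deterministic, seeded generators for every input the toolkit consumes.

Each generator emits both the data and its planted ground truth, so
downstream recovery tests never have to trust the module they exercise:

- :func:`make_micro_ontology` — a ~45-concept bilingual diabetes
  micro-ontology under SNOMED-CT-style top-level roots, containing every
  class the shipped clinical rules mention, each with a Chinese label, at
  least one English name and a sourced definition;
- :func:`make_target_ontology` — an English target ontology with planted
  subsumptions plus the mapping table that aligns micro-ontology concepts
  into it (ground truth for hierarchy-induction recovery);
- :func:`make_corpus` — documents embedding planted terms in controlled
  numbers of distinct documents, plus grade/degree and stoplist noise,
  with the surviving-term table precomputed by bookkeeping;
- :func:`make_patients` — patient ABoxes with symptom subsets and test
  values placed around the rule thresholds, plus the closure the four
  shipped rules must derive, computed by closed-form bookkeeping (never
  by running the inference engine).

Every generator draws from its own ``random.Random`` stream derived from
the single seed, so adding one generator cannot shift another's output;
the two published worked scenarios (the four-symptom patient with fasting
glucose 8.0 mmol/L, and patient_b with type 2 diabetes and BMI 28) are
hard-coded, not sampled.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from cdmo.crossmap import MappingRecord
from cdmo.onto_core import (
    Concept,
    DefinitionRecord,
    OntologyGraph,
    PropertyDef,
    concept_iri,
)
from cdmo.term_harvest import (
    DEFAULT_STOPLIST,
    GRADE_DEGREE_RE,
    Document,
)

__all__ = [
    "FixtureSpec",
    "make_micro_ontology",
    "make_target_ontology",
    "make_corpus",
    "make_patients",
    "RULE_CLASS_NAMES",
    "CANONICAL_INDIVIDUALS",
]


@dataclass
class FixtureSpec:
    """Bundle of generator parameters; defaults are the study conditions."""

    seed: int = 7
    n_docs: int = 20
    n_patients: int = 12
    min_docs: int = 3
    threshold_margins: tuple = (-1.0, -0.1, 0.0, 0.1, 1.0)
    planted_term_freqs: Optional[dict[str, int]] = None


# ---------------------------------------------------------------------
# micro-ontology

#: English names of every class the shipped rules mention
RULE_CLASS_NAMES = [
    "patient",
    "polyphagia",
    "polyuria",
    "polydipsia",
    "weight loss",
    "fasting blood glucose measurement",
    "diabetes mellitus",
    "type 2 diabetes mellitus",
    "body mass index",
    "orlistat",
    "glucagon-like peptide-1 receptor agonist",
    "lifestyle therapy",
    "renal insufficiency",
    "metformin",
    "hypoglycemia",
    "sugary food",
    "glucose",
]

# (zh label, [en names], parent zh label or None for roots, definition, source)
_CONCEPTS: list[tuple] = [
    # SNOMED-CT-style first-level roots
    ("临床表现", ["clinical finding"], None, "疾病、症状、体征等临床观察所见的总称。", "termonline"),
    ("过程", ["procedure"], None, "为诊断、治疗或预防目的而执行的医疗活动。", "termonline"),
    ("物质", ["substance"], None, "具有确定化学组成的物质实体。", "termonline"),
    ("药物或生物制品", ["pharmaceutical/biologic product"], None, "用于预防、诊断或治疗疾病的药品或生物制品。", "termonline"),
    ("可观察实体", ["observable entity"], None, "可以被观察或测量并赋值的实体。", "termonline"),
    ("身体结构", ["body structure"], None, "人体的解剖学结构。", "termonline"),
    ("社会环境", ["social context"], None, "与医疗活动相关的社会角色与环境因素。", "manual"),
    # clinical findings
    ("疾病", ["disorder", "disease"], "临床表现", "机体在致病因素作用下发生的异常生命活动过程。", "termonline"),
    ("症状", ["symptom"], "临床表现", "患者主观感受到的异常表现。", "baidu"),
    ("糖尿病", ["diabetes mellitus"], "疾病", "以慢性高血糖为特征的代谢性疾病，由胰岛素分泌缺陷或作用障碍引起。", "termonline"),
    ("1型糖尿病", ["type 1 diabetes mellitus"], "糖尿病", "因胰岛β细胞破坏导致胰岛素绝对缺乏的糖尿病类型。", "termonline"),
    ("2型糖尿病", ["type 2 diabetes mellitus"], "糖尿病", "以胰岛素抵抗为主伴胰岛素分泌相对不足的糖尿病类型。", "termonline"),
    ("妊娠期糖尿病", ["gestational diabetes mellitus"], "糖尿病", "妊娠期间首次发生或发现的糖代谢异常。", "CHPO"),
    ("特殊类型糖尿病", ["special type diabetes mellitus"], "糖尿病", "由特定病因（如单基因缺陷、药物）引起的糖尿病。", "baidu"),
    ("肾功能不全", ["renal insufficiency"], "疾病", "肾脏排泄代谢废物及调节水电解质功能下降的状态。", "baidu"),
    ("低血糖", ["hypoglycemia"], "疾病", "血浆葡萄糖浓度低于正常下限引起交感兴奋或神经缺糖症状的状态。", "termonline"),
    ("视网膜病变", ["retinopathy", "retinal disorder"], "疾病", "累及视网膜的各类病理改变的总称。", "MedDRA"),
    ("糖尿病视网膜病变", ["diabetic retinopathy", "retinopathy due to diabetes"], "疾病", "糖尿病微血管病变累及视网膜所致的病变，是糖尿病的慢性并发症。", "termonline"),
    ("酸中毒", ["acidosis"], "疾病", "体液酸碱平衡紊乱中pH下降的病理状态。", "termonline"),
    ("乳酸性酸中毒", ["lactic acidosis"], "酸中毒", "血乳酸水平升高引起的代谢性酸中毒。", "termonline"),
    ("黑棘皮病", ["acanthosis nigricans"], "疾病", "以皮肤色素沉着和天鹅绒样增厚为特征的皮肤病，常与胰岛素抵抗相关。", "baidu"),
    ("高渗性高血糖状态", ["hyperosmolar hyperglycemic state", "hyperglycemic hyperosmolar status"], "疾病", "以严重高血糖、高渗透压和脱水为特征的糖尿病急性并发症。", "termonline"),
    ("多食", ["polyphagia"], "症状", "食欲亢进、进食量明显增多的症状。", "CHPO"),
    ("多尿", ["polyuria"], "症状", "24小时尿量明显超过正常范围的症状。", "CHPO"),
    ("多饮", ["polydipsia"], "症状", "饮水量异常增多的症状。", "CHPO"),
    ("体重减轻", ["weight loss"], "症状", "非意愿性的体重下降。", "MedDRA"),
    ("乏力", ["fatigue", "malaise", "weakness"], "症状", "自觉疲乏、体力下降的症状。", "termonline"),
    # procedures
    ("空腹血糖测定", ["fasting blood glucose measurement"], "过程", "禁食至少8小时后测定血浆葡萄糖浓度的检验。", "termonline"),
    ("肌酐测定", ["creatinine measurement"], "过程", "对样本中肌酐含量的定量检测。", "termonline"),
    ("糖化血红蛋白测定", ["hemoglobin A1c measurement"], "过程", "测定血红蛋白A1c占总血红蛋白比例的检验，反映近2-3个月血糖水平。", "termonline"),
    ("生活方式干预", ["lifestyle therapy", "lifestyle intervention"], "过程", "通过饮食、运动和行为调整进行疾病防治的非药物措施。", "baidu"),
    # substances
    ("肌酐", ["creatinine"], "物质", "肌肉组织中肌酸的代谢产物，经肾脏排泄。", "termonline"),
    ("葡萄糖", ["glucose"], "物质", "己糖类单糖，是机体的主要供能物质。", "termonline"),
    ("糖化血红蛋白", ["glycated hemoglobin", "glycated hemoglobin-A1c"], "物质", "血红蛋白与葡萄糖非酶促结合形成的产物。", "termonline"),
    ("含糖食物", ["sugary food"], "物质", "含有可快速吸收碳水化合物的食物。", "manual"),
    ("类固醇激素", ["steroid hormone"], "物质", "以环戊烷多氢菲为母核的激素类化合物。", "termonline"),
    ("肾上腺皮质激素", ["adrenal cortex hormone", "adrenocorticoid"], "类固醇激素", "肾上腺皮质受促肾上腺皮质激素刺激产生的类固醇激素，按生理特性分为盐皮质激素和糖皮质激素。", "termonline"),
    ("糖皮质激素", ["glucocorticoid"], "肾上腺皮质激素", "调节糖、蛋白质和脂肪代谢的肾上腺皮质激素。", "termonline"),
    ("盐皮质激素", ["mineralocorticoid"], "肾上腺皮质激素", "调节水盐代谢的肾上腺皮质激素。", "termonline"),
    # pharmaceutical / biologic products
    ("二甲双胍", ["metformin"], "药物或生物制品", "双胍类口服降糖药，2型糖尿病的一线治疗药物。", "termonline"),
    ("奥利司他", ["orlistat"], "药物或生物制品", "胃肠道脂肪酶抑制剂，用于肥胖症的治疗。", "baidu"),
    ("胰高糖素样肽-1受体激动剂", ["glucagon-like peptide-1 receptor agonist", "GLP-1 receptor agonist"], "药物或生物制品", "激动GLP-1受体以促进胰岛素分泌并抑制食欲的降糖药物。", "termonline"),
    # observable entities
    ("体重指数", ["body mass index", "BMI"], "可观察实体", "体重（千克）除以身高（米）平方所得的指数，用于评估肥胖程度。", "termonline"),
    # body structures
    ("视网膜", ["retina"], "身体结构", "眼球壁内层的感光神经组织。", "termonline"),
    ("肾脏", ["kidney"], "身体结构", "泌尿系统的主要器官，生成尿液并调节内环境。", "termonline"),
    # social context
    ("患者", ["patient"], "社会环境", "接受医疗观察、诊断或治疗的个体。", "manual"),
]

_ANNOTATIONS = {
    "空腹血糖测定": {"正常参考值": "3.9-6.1 mmol/L", "诊断切点": "7.0 mmol/L"},
    "体重指数": {"正常参考值": "18.5-23.9 kg/m2", "诊断切点": "27 kg/m2"},
    "二甲双胍": {"药物常用剂量": "500-2000 mg/日", "用药频次": "每日2-3次"},
}

_SYNONYMS = {
    "黑棘皮病": ["黑棘皮症"],
    "乏力": ["疲劳"],
    "糖尿病视网膜病变": ["糖网病"],
    "高渗性高血糖状态": ["高渗高血糖综合征"],
}


def _object_properties() -> dict[str, PropertyDef]:
    cf = concept_iri("临床表现")
    proc = concept_iri("过程")
    drug = concept_iri("药物或生物制品")
    obs = concept_iri("可观察实体")
    subst = concept_iri("物质")
    pat = concept_iri("患者")
    props: dict[str, PropertyDef] = {}

    def add(name_zh, name_en, parent=None, domain=(), range_=()):
        props[name_zh] = PropertyDef(
            name_zh=name_zh, name_en=name_en, kind="object", parent=parent,
            domain=list(domain), range=list(range_),
        )

    # property families with sub-property hierarchies
    add("并发症", "has complication", None, [cf, proc], [cf])
    for zh, en in [
        ("常见并发症", "has common complications"),
        ("特有的并发症", "has specific complications"),
        ("急性并发症", "has acute complications"),
        ("慢性并发症", "has chronic complications"),
        ("近期并发症", "has short term complications"),
        ("远期并发症", "has long term complications"),
    ]:
        add(zh, en, "并发症", [cf, proc], [cf])
    add("治疗药物", "therapeutic drug", None, [cf, proc], [drug])
    for zh, en in [
        ("一线药物", "first line therapeutic drug"),
        ("二线药物", "second line therapeutic drug"),
        ("首选药物", "preferred drug"),
        ("慎用药物", "cautiously use drug"),
    ]:
        add(zh, en, "治疗药物", [cf, proc], [drug])
    add("症状", "has symptom", None, [cf], [cf])
    for zh, en in [
        ("典型症状", "has major feature"),
        ("少见症状", "has rare symptom"),
        ("首发症状", "has first symptom"),
        ("常见症状", "has common symptom"),
    ]:
        add(zh, en, "症状", [cf], [cf])
    # rule vocabulary
    add("患者有症状", "patient_has_symptom", None, [pat], [cf])
    add("患者有检查", "patient_has_test", None, [pat], [proc])
    add("患者有诊断", "patient_has_diagnosis", None, [pat], [cf])
    add("患者有可观察实体", "patient_has_observable_entity", None, [pat], [obs])
    add("患者有治疗", "patient_has_therapy", None, [pat], [proc])
    add("患者有治疗药物", "patient_has_therapy_drug", None, [pat], [drug])
    add("患者有禁忌药物", "patient_has_constraindication_drug", None, [pat], [drug])
    add("增加摄入", "increase_intake", None, [pat], [subst])
    # annotation properties
    for zh, en in [
        ("正常参考值", "normal reference value"),
        ("诊断切点", "diagnostic cut-off value"),
        ("来源语句", "source sentences"),
        ("英文名称", "English names"),
        ("药物常用剂量", "common drug dosage"),
        ("用药频次", "drug administration frequency"),
    ]:
        props[zh] = PropertyDef(name_zh=zh, name_en=en, kind="annotation")
    return props


def make_micro_ontology(seed: int = 7) -> OntologyGraph:
    """Build the bilingual diabetes micro-ontology.

    Content is fully determined (the seed only keeps the generator
    signature uniform): same input, byte-identical serialisation.
    """
    graph = OntologyGraph()
    for label_zh, labels_en, parent_zh, definition, source in _CONCEPTS:
        graph.add_concept(
            Concept(
                iri=concept_iri(label_zh),
                label_zh=label_zh,
                labels_en=list(labels_en),
                synonyms_zh=list(_SYNONYMS.get(label_zh, [])),
                definition=DefinitionRecord(definition, source),
                annotations=dict(_ANNOTATIONS.get(label_zh, {})),
                parents=[concept_iri(parent_zh)] if parent_zh else [],
            )
        )
    graph.properties = _object_properties()
    graph.roots = sorted(
        concept_iri(zh) for zh, _, parent, _, _ in _CONCEPTS if parent is None
    )
    graph.validate()
    return graph


# ---------------------------------------------------------------------
# target ontology + planted mappings

# (target id, English label, parent target id)
_TARGET_CLASSES = [
    ("T000", "SNOMED CT concept", None),
    ("T100", "disease (disorder)", "T000"),
    ("T110", "diabetes mellitus (disorder)", "T100"),
    ("T111", "type 1 diabetes mellitus (disorder)", "T110"),
    ("T112", "type 2 diabetes mellitus (disorder)", "T110"),
    ("T113", "gestational diabetes mellitus (disorder)", "T110"),
    ("T120", "retinal disorder (disorder)", "T100"),
    ("T121", "retinopathy due to diabetes (disorder)", "T120"),
    ("T130", "acidosis (disorder)", "T100"),
    ("T131", "lactic acidosis (disorder)", "T130"),
    ("T140", "hypoglycemia (disorder)", "T100"),
    ("T150", "renal insufficiency (disorder)", "T100"),
    ("T160", "acanthosis nigricans (disorder)", "T100"),
    ("T170", "hyperosmolar hyperglycemic syndrome (disorder)", "T100"),
    ("T180", "Fatigue", "T100"),
    ("T181", "Weakness", "T180"),
    ("T182", "Asthenia", "T180"),
    ("T200", "steroid hormone (substance)", "T000"),
    ("T210", "adrenal cortex hormone (substance)", "T200"),
    ("T211", "glucocorticoid (substance)", "T210"),
    ("T212", "mineralocorticoid (substance)", "T210"),
]

# zh label of source concept -> target id (the planted alignment)
_PLANTED_MAPPING = {
    "疾病": "T100",
    "糖尿病": "T110",
    "1型糖尿病": "T111",
    "2型糖尿病": "T112",
    "妊娠期糖尿病": "T113",
    "视网膜病变": "T120",
    "糖尿病视网膜病变": "T121",
    "酸中毒": "T130",
    "乳酸性酸中毒": "T131",
    "低血糖": "T140",
    "肾功能不全": "T150",
    "黑棘皮病": "T160",
    "高渗性高血糖状态": "T170",
    "类固醇激素": "T200",
    "肾上腺皮质激素": "T210",
    "糖皮质激素": "T211",
    "盐皮质激素": "T212",
}

TARGET_ONTOLOGY_NAME = "SNOMEDCT"


def make_target_ontology(
    seed: int = 7,
) -> tuple[OntologyGraph, list[MappingRecord], list[tuple[str, str]]]:
    """English target ontology, planted mapping table, planted edges.

    Returns ``(target_graph, mappings, planted_edges)`` where
    ``planted_edges`` is the ground-truth list of (child_iri, parent_iri)
    source edges that mapping-based induction must recover: exactly the
    Hasse relations of the target hierarchy restricted to mapped classes.
    """
    target = OntologyGraph()
    for tid, label, parent in _TARGET_CLASSES:
        target.add_concept(
            Concept(
                iri=tid,
                label_zh=label,
                labels_en=[label],
                definition=DefinitionRecord(f"Target class {label}.", "manual"),
                parents=[parent] if parent else [],
            )
        )
    target.roots = ["T000"]
    target.validate()

    mappings = [
        MappingRecord(concept_iri(zh), TARGET_ONTOLOGY_NAME, tid, "exact")
        for zh, tid in sorted(_PLANTED_MAPPING.items())
    ]

    inv = {tid: zh for zh, tid in _PLANTED_MAPPING.items()}
    planted: list[tuple[str, str]] = []
    for tid, _, parent in _TARGET_CLASSES:
        if tid in inv and parent in inv:
            planted.append((concept_iri(inv[tid]), concept_iri(inv[parent])))
    return target, mappings, sorted(planted)


# ---------------------------------------------------------------------
# corpus

_DEFAULT_TERM_FREQS = {
    # term -> number of distinct documents it is planted in
    "糖尿病": 6,
    "低血糖": 4,
    "二甲双胍": 3,
    "视网膜病变": 3,
    "糖化血红蛋白": 4,
    "多尿": 5,   # frequent but absent from the lexicon-presence set
    "胰岛素": 2,  # below the document threshold
    "体重减轻": 1,
}

#: surfaces with a dictionary / term-bank / encyclopedia entry
_DEFAULT_LEXICON_PRESENCE = {
    "糖尿病", "低血糖", "二甲双胍", "视网膜病变", "糖化血红蛋白",
    "胰岛素", "体重减轻", "1级", "3期", "全部",
}

_NOISE_TERMS = ["1级", "3期", "全部"]


def make_corpus(
    seed: int = 7, spec: Optional[FixtureSpec] = None
) -> tuple[list[Document], dict]:
    """Synthetic guideline-like corpus with controlled document frequencies.

    Returns ``(documents, truth)``; ``truth`` records the planted per-term
    document counts, the automaton lexicon, the lexicon-presence set, and
    the terms that must survive the exclusion -> lexicon+frequency filter
    pipeline at ``spec.min_docs``.
    """
    spec = spec or FixtureSpec(seed=seed)
    rng = random.Random((seed * 1_000_003 + 1) % (2**31))
    freqs = dict(spec.planted_term_freqs or _DEFAULT_TERM_FREQS)
    n_docs = max(spec.n_docs, max(freqs.values()))
    placements: dict[int, list[str]] = {i: [] for i in range(n_docs)}
    for term in sorted(freqs):
        for doc_idx in sorted(rng.sample(range(n_docs), freqs[term])):
            placements[doc_idx].append(term)
    # noise appears in many documents but must never survive the pipeline
    for noise in _NOISE_TERMS:
        for doc_idx in sorted(rng.sample(range(n_docs), min(4, n_docs))):
            placements[doc_idx].append(noise)
    documents = []
    for i in range(n_docs):
        terms = placements[i]
        rng.shuffle(terms)
        text = "。".join(terms) + "。" if terms else "无相关内容。"
        documents.append(Document(doc_id=f"doc{i:03d}", text=text, source="synthetic"))
    lexicon = sorted(set(freqs) | set(_NOISE_TERMS))
    survivors = sorted(
        t
        for t, f in freqs.items()
        if t in _DEFAULT_LEXICON_PRESENCE
        and f >= spec.min_docs
        and t not in DEFAULT_STOPLIST
        and not GRADE_DEGREE_RE.match(t)
    )
    truth = {
        "planted_freqs": freqs,
        "lexicon": lexicon,
        "lexicon_presence": set(_DEFAULT_LEXICON_PRESENCE),
        "noise_terms": list(_NOISE_TERMS),
        "survivors": survivors,
        "min_docs": spec.min_docs,
    }
    return documents, truth


# ---------------------------------------------------------------------
# patients

#: shared ABox individuals: canonical instance of each rule-relevant class
CANONICAL_INDIVIDUALS = {
    "dm_canonical": "糖尿病",
    "t2dm_canonical": "2型糖尿病",
    "renal_insufficiency_canonical": "肾功能不全",
    "hypoglycemia_canonical": "低血糖",
    "polyphagia_canonical": "多食",
    "polyuria_canonical": "多尿",
    "polydipsia_canonical": "多饮",
    "weight_loss_canonical": "体重减轻",
    "orlistat_canonical": "奥利司他",
    "glp1ra_canonical": "胰高糖素样肽-1受体激动剂",
    "lifestyle_therapy_canonical": "生活方式干预",
    "metformin_canonical": "二甲双胍",
    "sugary_food_canonical": "含糖食物",
    "glucose_canonical": "葡萄糖",
}

_SYMPTOM_INDIVIDUALS = [
    "polyphagia_canonical",
    "polyuria_canonical",
    "polydipsia_canonical",
    "weight_loss_canonical",
]

#: individuals typed under diabetes mellitus — targets of Diagnosis_1
_DIABETES_TYPED = ["dm_canonical", "t2dm_canonical"]


@dataclass
class _Patient:
    name: str
    symptoms: list[str]  # subset of _SYMPTOM_INDIVIDUALS
    fbg: Optional[float] = None
    bmi: Optional[float] = None
    asserted_diagnoses: list[str] = field(default_factory=list)


def _patient_truth(p: _Patient) -> set[tuple]:
    """Closure of the four shipped rules for one patient, by bookkeeping.

    The class atom over diabetes mellitus matches every individual typed
    under it (subsumption), so a qualifying patient is diagnosed with both
    the diabetes-mellitus and the type-2 canonical individuals; a derived
    type-2 diagnosis can in turn satisfy the therapy and contraindication
    rules.  Derived never includes what was asserted.
    """
    asserted = {("obj", "patient_has_diagnosis", p.name, d) for d in p.asserted_diagnoses}
    derived: set[tuple] = set()

    diagnoses = set(p.asserted_diagnoses)
    if set(p.symptoms) == set(_SYMPTOM_INDIVIDUALS) and p.fbg is not None and p.fbg >= 7.0:
        for d in _DIABETES_TYPED:
            fact = ("obj", "patient_has_diagnosis", p.name, d)
            diagnoses.add(d)
            if fact not in asserted:
                derived.add(fact)
    if "t2dm_canonical" in diagnoses and p.bmi is not None and p.bmi >= 27:
        derived |= {
            ("obj", "patient_has_therapy", p.name, "lifestyle_therapy_canonical"),
            ("obj", "patient_has_therapy_drug", p.name, "orlistat_canonical"),
            ("obj", "patient_has_therapy_drug", p.name, "glp1ra_canonical"),
        }
    if "t2dm_canonical" in diagnoses and "renal_insufficiency_canonical" in diagnoses:
        derived.add(
            ("obj", "patient_has_constraindication_drug", p.name, "metformin_canonical")
        )
    if "hypoglycemia_canonical" in diagnoses:
        derived |= {
            ("obj", "increase_intake", p.name, "sugary_food_canonical"),
            ("obj", "increase_intake", p.name, "glucose_canonical"),
        }
    return derived


def make_patients(
    seed: int = 7,
    n: int = 12,
    margins: Sequence[float] = (-1.0, -0.1, 0.0, 0.1, 1.0),
) -> tuple[dict, dict[str, list[list]]]:
    """Patient ABox (JSON-ready dict) plus per-patient ground truth.

    The first two patients are the published worked scenarios: the
    four-symptom patient with fasting blood glucose 8.0 mmol/L, and
    patient_b with an asserted type 2 diabetes diagnosis and BMI 28.
    Remaining patients are sampled with symptom subsets and test values at
    threshold + margin (exactly-at-threshold included via margin 0.0).
    """
    rng = random.Random((seed * 1_000_003 + 2) % (2**31))
    patients = [
        _Patient("patient_a", list(_SYMPTOM_INDIVIDUALS), fbg=8.0),
        _Patient("patient_b", [], bmi=28.0, asserted_diagnoses=["t2dm_canonical"]),
    ]
    for i in range(max(n - 2, 0)):
        n_sym = rng.choice([2, 3, 4, 4])
        symptoms = sorted(rng.sample(_SYMPTOM_INDIVIDUALS, n_sym))
        fbg = round(7.0 + rng.choice(list(margins)), 2)
        bmi = float(27 + rng.choice([-3, -1, 0, 1, 3])) if rng.random() < 0.7 else None
        asserted = []
        if rng.random() < 0.35:
            asserted.append("t2dm_canonical")
        if rng.random() < 0.25:
            asserted.append("renal_insufficiency_canonical")
        if rng.random() < 0.25:
            asserted.append("hypoglycemia_canonical")
        patients.append(
            _Patient(f"patient_{i:02d}", symptoms, fbg=fbg, bmi=bmi,
                     asserted_diagnoses=asserted)
        )

    individuals = [
        {"name": name, "types": [concept_iri(zh)]}
        for name, zh in sorted(CANONICAL_INDIVIDUALS.items())
    ]
    object_assertions: list[list] = []
    data_assertions: list[list] = []
    for p in patients:
        individuals.append({"name": p.name, "types": [concept_iri("患者")]})
        for s in p.symptoms:
            object_assertions.append(["patient_has_symptom", p.name, s])
        if p.fbg is not None:
            test = f"{p.name}_fbg"
            individuals.append({"name": test, "types": [concept_iri("空腹血糖测定")]})
            object_assertions.append(["patient_has_test", p.name, test])
            data_assertions.append(["test_has_value", test, p.fbg, "mmol/L"])
        if p.bmi is not None:
            obs = f"{p.name}_bmi"
            individuals.append({"name": obs, "types": [concept_iri("体重指数")]})
            object_assertions.append(["patient_has_observable_entity", p.name, obs])
            data_assertions.append(["observable_entity_has_value", obs, p.bmi, "kg/m2"])
        for d in p.asserted_diagnoses:
            object_assertions.append(["patient_has_diagnosis", p.name, d])

    abox = {
        "individuals": individuals,
        "object_assertions": object_assertions,
        "data_assertions": data_assertions,
    }
    truth = {
        p.name: sorted(list(a) for a in _patient_truth(p)) for p in patients
    }
    return abox, truth
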