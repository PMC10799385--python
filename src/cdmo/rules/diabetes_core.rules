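# Patients with symptoms of polyphagia, polyuria, polydipsia and weight loss, and fasting blood glucose greater than or equal to 7 mmol/L, are predicted to have diabetes mellitus
Diagnosis_1: patient(?p) ^ polyphagia(?s1) ^ polyuria(?s2) ^ polydipsia(?s3) ^ weight_loss(?s4) ^ fasting_blood_glucose_measurement(?t1) ^ diabetes_mellitus(?d1) ^ patient_has_symptom(?p, ?s1) ^ patient_has_symptom(?p, ?s2) ^ patient_has_symptom’(?p, ?s3) ^ patient_has_symptom(?p, ?s4) ^ patient_has_test(?p, ?t1) ^ test_has_value(?t1, ?v1) ^ swrlb:greaterThanOrEqual(?v1, 7.0)—> patient_has_diagnosis(?p, ?d1)

# If the patient has type 2 diabetes and the body mass index is above 27, lifestyle interventions and treatment with glucagon-like peptide 1 receptor agonist and orlistat medications are recommended
Therapy_1: patient(?p) ^ type_2_diabetes_mellitus(?d) ^ body_mass_index(?o) ^ orlistat(?drug1) ^ glucagon_like_peptide_1_receptor_agonist(?drug2) ^ lifestyle_therapy(?therapy) ^ patient_has_diagnosis(?p, ?d) ^ patient_has_observable_entity(?p, ?o) ^ observable_entity_has_value(?o, ?v) ^ swrlb:greaterThanOrEqual(?v, 27)—> patient_has_therapy(?p, ?therapy) ^ patient_has_therapy_drug(?p, ?drug1) ^ patient_has_therapy_drug(?p, ?drug2)

# Patients with type 2 diabetes who have renal insufficiency should not take metformin
Constraindication_drug_1: patient(?p) ^ CDMO:renal_insufficiency(?d1) ^ CDMO:type_2_diabetes_mellitus(?d2) ^ CDMO:metformin(?drug) ^ cdmo:patient_has_diagnosis(?p, ?d1) ^ cdmo:patient_has_diagnosis(?p, ?d2)—> CDMO:patient_has_constraindication_drug(?p, ?drug)

# Patients with hypoglycemia are advised to increase their intake of glucose and sugary foods
Diet_1: patient(?p) ^ hypoglycemia(?s1) ^ sugary_food(?f1) ^ glucose(?f2) ^ patient_has_diagnosis(?p,?s1)—> increase_intake(?p, ?f1) ^ increase_intake(?p,?f2)
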