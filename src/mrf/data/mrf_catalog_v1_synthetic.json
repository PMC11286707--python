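{
  "version": "1.0-synthetic",
  "provenance": "Reconstructed MRF (Medication-Related Fall) catalog. The published final tool lists 19 medication classes (10 high-risk, 8 moderate-risk, 1 low-risk). Twelve classes and their tiers are fixed by the published narrative (high: antidepressants, benzodiazepines, hypnotics, antipsychotics, anticholinergics, centrally acting antihypertensives, direct arterial vasodilators, non-selective alpha-blockers, loop diuretics, first-generation anti-epileptics; moderate: beta-blockers, ACEIs/ARBs, dihydropyridine CCBs, thiazides, second-generation anti-epileptics). The remaining three moderate-risk classes and the single low-risk class are plausible reconstructions, not a verbatim transcription, as are all member drug lists. SNRIs, selective alpha-blockers, prochlorperazine, cyclizine, dopaminergic anti-Parkinson's medications, SSRIs and eye preparations did not reach consensus and are deliberately absent.",
  "classes": [
    {
      "class_id": "antidepressants_tca",
      "name": "antidepressants (tricyclic and related)",
      "tier": "high",
      "mechanism": "Sedation, drowsiness, orthostatic hypotension and anticholinergic effects impairing alertness and balance.",
      "members": ["amitriptyline", "nortriptyline", "imipramine", "clomipramine", "dosulepin", "doxepin", "trazodone", "mirtazapine"],
      "synonyms": {"dothiepin": "dosulepin"}
    },
    {
      "class_id": "benzodiazepines",
      "name": "benzodiazepines",
      "tier": "high",
      "mechanism": "Sedation and impaired psychomotor function, balance and reaction time.",
      "members": ["diazepam", "lorazepam", "temazepam", "nitrazepam", "chlordiazepoxide", "alprazolam", "clonazepam"],
      "synonyms": {"valium": "diazepam"}
    },
    {
      "class_id": "z_drug_hypnotics",
      "name": "hypnotics (Z-drugs)",
      "tier": "high",
      "mechanism": "Sedation, drowsiness and impaired coordination, particularly with night-time rising.",
      "members": ["zopiclone", "zolpidem", "zaleplon"],
      "synonyms": {}
    },
    {
      "class_id": "antipsychotics",
      "name": "antipsychotics",
      "tier": "high",
      "mechanism": "Sedation, extrapyramidal effects, gait disturbance and orthostatic hypotension.",
      "members": ["haloperidol", "risperidone", "olanzapine", "quetiapine", "chlorpromazine", "aripiprazole", "amisulpride"],
      "synonyms": {}
    },
    {
      "class_id": "anticholinergics",
      "name": "anticholinergics",
      "tier": "high",
      "mechanism": "Confusion, blurred vision, sedation and delirium increasing falls risk.",
      "members": ["oxybutynin", "tolterodine", "solifenacin", "hyoscine", "procyclidine", "trihexyphenidyl"],
      "synonyms": {"hyoscine butylbromide": "hyoscine", "benzhexol": "trihexyphenidyl"}
    },
    {
      "class_id": "centrally_acting_antihypertensives",
      "name": "centrally acting antihypertensives",
      "tier": "high",
      "mechanism": "Orthostatic hypotension and sedation via central sympatholytic action.",
      "members": ["clonidine", "moxonidine", "methyldopa"],
      "synonyms": {}
    },
    {
      "class_id": "direct_vasodilators",
      "name": "direct arterial vasodilators",
      "tier": "high",
      "mechanism": "Marked vasodilation causing hypotension and orthostatic symptoms.",
      "members": ["hydralazine", "minoxidil"],
      "synonyms": {}
    },
    {
      "class_id": "nonselective_alpha_blockers",
      "name": "non-selective alpha-blockers",
      "tier": "high",
      "mechanism": "Orthostatic and first-dose hypotension through alpha-1 adrenoceptor blockade.",
      "members": ["doxazosin", "prazosin", "terazosin", "indoramin"],
      "synonyms": {}
    },
    {
      "class_id": "loop_diuretics",
      "name": "loop diuretics",
      "tier": "high",
      "mechanism": "Hypovolaemia and orthostatic hypotension; urinary urgency prompting rushed mobilisation.",
      "members": ["furosemide", "bumetanide", "torasemide"],
      "synonyms": {"frusemide": "furosemide", "lasix": "furosemide", "torsemide": "torasemide"}
    },
    {
      "class_id": "first_gen_antiepileptics",
      "name": "first-generation anti-epileptics",
      "tier": "high",
      "mechanism": "Sedation, dizziness and ataxia; narrow therapeutic index with dose-related neurotoxicity.",
      "members": ["phenytoin", "carbamazepine", "phenobarbital", "primidone", "valproate"],
      "synonyms": {"sodium valproate": "valproate", "valproic acid": "valproate", "phenobarbitone": "phenobarbital"}
    },
    {
      "class_id": "beta_blockers",
      "name": "beta-blockers",
      "tier": "moderate",
      "mechanism": "Bradycardia and hypotension; falls risk considered patient-specific, chiefly with orthostatic hypotension.",
      "members": ["atenolol", "bisoprolol", "metoprolol", "propranolol", "carvedilol", "nebivolol"],
      "synonyms": {}
    },
    {
      "class_id": "acei_arb",
      "name": "ACE inhibitors / angiotensin receptor blockers",
      "tier": "moderate",
      "mechanism": "Hypotension, especially orthostatic and first-dose; risk dose- and time-dependent.",
      "members": ["ramipril", "lisinopril", "enalapril", "perindopril", "losartan", "candesartan", "valsartan", "irbesartan"],
      "synonyms": {}
    },
    {
      "class_id": "dihydropyridine_ccb",
      "name": "dihydropyridine calcium channel blockers",
      "tier": "moderate",
      "mechanism": "Vasodilation and hypotension, particularly in combination with other antihypertensives.",
      "members": ["amlodipine", "felodipine", "nifedipine", "lercanidipine"],
      "synonyms": {}
    },
    {
      "class_id": "thiazides",
      "name": "thiazide and thiazide-like diuretics",
      "tier": "moderate",
      "mechanism": "Hypovolaemia, hyponatraemia and orthostatic hypotension.",
      "members": ["bendroflumethiazide", "hydrochlorothiazide", "indapamide", "chlortalidone"],
      "synonyms": {"bendrofluazide": "bendroflumethiazide", "chlorthalidone": "chlortalidone"}
    },
    {
      "class_id": "second_gen_antiepileptics",
      "name": "second-generation anti-epileptics",
      "tier": "moderate",
      "mechanism": "Dizziness and somnolence; adverse-event profile more favourable than first-generation agents.",
      "members": ["lamotrigine", "levetiracetam", "gabapentin", "pregabalin", "topiramate", "oxcarbazepine"],
      "synonyms": {}
    },
    {
      "class_id": "opioids",
      "name": "opioids",
      "tier": "moderate",
      "mechanism": "Sedation, dizziness and confusion, especially in combination with other CNS depressants.",
      "members": ["morphine", "oxycodone", "codeine", "tramadol", "fentanyl", "buprenorphine"],
      "synonyms": {"co-codamol": "codeine"}
    },
    {
      "class_id": "nitrates",
      "name": "nitrates",
      "tier": "moderate",
      "mechanism": "Vasodilation causing hypotension and syncope, especially in combination.",
      "members": ["isosorbide mononitrate", "isosorbide dinitrate", "glyceryl trinitrate"],
      "synonyms": {"gtn": "glyceryl trinitrate", "nitroglycerin": "glyceryl trinitrate"}
    },
    {
      "class_id": "sulfonylureas",
      "name": "sulfonylureas",
      "tier": "moderate",
      "mechanism": "Hypoglycaemia causing dizziness, confusion and unsteadiness, especially in combination.",
      "members": ["gliclazide", "glimepiride", "glipizide", "glibenclamide"],
      "synonyms": {"glyburide": "glibenclamide"}
    },
    {
      "class_id": "cardiac_glycosides",
      "name": "cardiac glycosides (digoxin)",
      "tier": "low",
      "mechanism": "Bradycardia and arrhythmia possibly contributing to syncope, particularly in combination; direct published evidence of increased falls risk is lacking.",
      "members": ["digoxin", "digitoxin"],
      "synonyms": {}
    }
  ]
}
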