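# Template bank for synthetic VTE imaging reports.
# Slot values: the FIRST entry of each lexicon is the default; the rest are
# synonyms chosen with probability `synonym_rate`.
# Constraint: no template may render any literal class-label token
# ("PE only", "Proximal DVT", "Distal DVT", "Thrombophlebitis", "Other DVT",
# "DVT and PE", "No DVT or PE"), case-insensitively.

lexicons:
  laterality: [right, left, bilateral]
  hedge: [Acute, Probable acute, Suspected acute, Likely acute]
  occl: [occlusive, near-occlusive, partially occlusive, non-occlusive]
  pe_branch: [segmental, subsegmental, truncal, lobar]
  prox_site:
    - femoral vein
    - popliteal vein
    - common femoral vein
    - external iliac vein
    - common iliac vein
    - inferior vena cava
  dist_site:
    - soleal vein
    - calf vein
    - gastrocnemius vein
    - posterior tibial vein
    - peroneal vein
  saph_site:
    - great saphenous vein
    - small saphenous vein
  other_site:
    - subclavian vein
    - internal jugular vein
    - axillary vein
    - brachial vein
    - basilic vein
  neg_verb: [identified, seen, demonstrated, detected]
  patent_adj: [patent, widely patent]

modality_headers:
  chest CT:
    - "Contrast-enhanced computed tomography of the chest."
    - "Chest computed tomography with intravenous contrast."
  pulmonary artery CT angiography:
    - "Computed tomography angiography of the pulmonary arteries."
    - "Pulmonary arterial phase computed tomography angiogram."
  lower extremity vein CT:
    - "Computed tomography venography of the lower extremity veins."
    - "Lower extremity venous phase computed tomography."
  DVT CT:
    - "Dedicated computed tomography venography for deep venous evaluation."
    - "Indirect computed tomography venography of the deep veins."
  lower extremity vein duplex ultrasonography:
    - "Duplex ultrasonography of the lower extremity veins."
    - "Lower extremity venous duplex examination with compression."

classes:
  "No DVT or PE":
    - "No evidence of pulmonary embolism or deep venous thrombosis {neg_verb}."
    - "The deep veins are {patent_adj} and fully compressible; no intraluminal thrombus {neg_verb}."
    - "No filling defect within the pulmonary arteries or the deep venous system."
    - "Unremarkable study; no thromboembolic disease {neg_verb}."
  "PE only":
    - "{hedge} filling defect in the {pe_branch} pulmonary artery, consistent with pulmonary embolism."
    - "{hedge} pulmonary thromboembolism involving the {pe_branch} pulmonary arterial branches."
    - "Filling defects within the {pe_branch} pulmonary artery indicate acute pulmonary embolism. The visualized deep veins are {patent_adj}."
  "Proximal DVT":
    - "{hedge} {occl} thrombus within the {laterality} {prox_site}."
    - "{hedge} deep venous thrombosis involving the {laterality} {prox_site}."
    - "Echogenic clot distends the {laterality} {prox_site} with loss of compressibility. No pulmonary filling defect {neg_verb}."
  "Distal DVT":
    - "{hedge} {occl} thrombus confined to the {laterality} {dist_site}."
    - "{hedge} deep venous thrombosis limited to the {laterality} {dist_site}."
    - "Non-compressible {laterality} {dist_site} with intraluminal echogenic material. The proximal deep veins are {patent_adj}."
  "Thrombophlebitis":
    - "{hedge} superficial venous thrombosis of the {laterality} {saph_site}."
    - "Thrombosed {laterality} {saph_site} with surrounding inflammatory change."
    - "Non-compressible superficial {laterality} {saph_site}; the deep system is {patent_adj}."
  "Other DVT":
    - "{hedge} {occl} thrombus within the {laterality} {other_site}."
    - "{hedge} venous thrombosis involving the {laterality} {other_site}."
    - "Intraluminal filling defect of the {laterality} {other_site}, compatible with venous thrombosis."

distractors:
  - "Mild cardiomegaly is noted."
  - "Small right pleural effusion."
  - "Degenerative changes of the lumbar spine."
  - "Hepatic steatosis incidentally noted."
  - "No focal consolidation in the visualized lungs."
  - "Subcutaneous edema of the lower extremities."
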