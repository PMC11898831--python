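case,description
1,"54-year-old male, right-hand dominant manual laborer, untreated disease in the 4th ray with a 30° MCP contracture, no comorbidities, non-smoker, no alcohol."
2,"61-year-old male, right-hand dominant IT worker, untreated disease in the 4th ray with 35° MCP and 50° PIP contractures, hypertension, non-smoker, moderate alcohol."
3,"74-year-old female, right-hand dominant, disease in the 4th and 5th rays, 30° MCP and 80° PIP (5th), T2DM/HTN, active smoker, no alcohol. Previous needle aponeurotomy."
4,"44-year-old male, right-hand dominant manual laborer, palpable nodule in the palm but no contracture, no comorbidities, non-smoker, no alcohol."
5,"45-year-old male, right-hand dominant, mild disease with a 15° MCP contracture, no other digit involvement, no significant medical history, non-smoker, no alcohol."
6,"34-year-old male, right-hand dominant professional guitarist, palpable palmar nodule, no contracture, no comorbidities, non-smoker, no alcohol."
7,"79-year-old female, right-hand dominant, untreated disease in the 4th ray with 20° MCP and 50° PIP contracture, previously treated 5th ray with collagenase, HTN, prior MI, asthma, non-smoker, no alcohol."
8,"56-year-old male, left-hand dominant pianist, disease in the 4th/5th rays (5th: 40° MCP, 30° PIP; 4th: 10° MCP, 10° PIP), T2DM, occasional alcohol, non-smoker."
9,"83-year-old female, right-hand dominant, advanced disease of the 5th ray (30° MCP, 70° PIP), multiple recurrences, T2DM/HTN, non-smoker, no alcohol."
10,"86-year-old male, right-hand dominant, severe recurrent disease in multiple rays of both hands, multiple prior surgeries, T2DM, CAD (2 MIs), CKD stage III, AF on anticoagulation, non-smoker, no alcohol. Severe contractures limiting daily activities."
11,"74-year-old male, right-hand dominant, advanced recurrent disease in the left 4th finger, 2 prior limited fasciectomies, well-controlled HTN, stage II CKD, T2DM, former smoker, minimal alcohol. Severe flexion contractures with scarring."
12,"68-year-old female, right-hand dominant, recurrent disease in the 4th/5th rays, 40° MCP and 20° PIP in the 5th, T2DM, well-controlled HTN, ex-smoker, moderate alcohol. Prior needle aponeurotomy."
13,"74-year-old male, right-hand dominant, advanced recurrent disease of the 5th ray (50° MCP, 90° PIP), prior partial fasciectomy and PNA, T2DM, CKD III, AF on warfarin, ex-smoker, no alcohol. Marked scarring, limited ROM."
14,"68-year-old male, right-hand dominant, disease in the palmar fascia of the left hand, T2DM, HTN, CKD II, non-smoker, occasional alcohol, nodular thickening but no flexion contractures."
15,"62-year-old male, left-hand dominant, recurrent disease primarily in the 4th finger, prior partial fasciectomy (6 years ago) and collagenase injection (3 years ago). T2DM, hyperlipidemia, post-CABG, non-smoker, occasional alcohol. Now 25° MCP/10° PIP."
16,"52-year-old male, left-hand dominant, early-stage disease in the palm near the ring finger with minimal 10° MCP contracture, no comorbidities, non-smoker, no alcohol, mild functional impact (graphic designer)."
17,"49-year-old male, left-hand dominant mechanical engineer, early disease with a small palmar nodule, ~5° MCP contracture, no comorbidities, non-smoker, occasional alcohol, concerned about progression."
18,"72-year-old male, right-hand dominant, mild disease in the 3rd/4th rays, 15° MCP contracture at the 5th, HTN on meds, hypercholesterolemia, non-smoker, social alcohol, mild symptoms, frequent typing/writing."
19,"59-year-old male, right-hand dominant, untreated disease in the 4th/5th rays of the left hand (5th: 50° MCP, 50° PIP; 4th: 30° MCP, 30° PIP). Carpenter with T2DM, mild HTN, non-smoker, social alcohol, progressive contractures over 2 years."
20,"68-year-old male, right-hand dominant, moderate disease of the left 5th ray, 40° MCP and 70° PIP, well-controlled hypertension, non-smoker, social alcohol, physically active, progressive over 3 years with functional impairment."
21,"68-year-old male, left-hand dominant, severe recurrent disease of the left 4th finger (60° MCP, 80° PIP), prior PNA 3 years ago with temporary relief, well-controlled HTN, non-smoker, social alcohol, progressive over 2 years, reduced grip."
22,"50-year-old male, right-hand dominant, disease primarily in the left 4th ray, 25° MCP contracture, carpenter with no comorbidities, non-smoker, no alcohol, progressive over 2 years, mild functional impact."
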