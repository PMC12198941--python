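# Tuscany 17-device cohort, first semester 2024: transcribed cell-by-cell from the published
# characteristics table of the high-tech devices (risk class IIb/III) evaluated by the regional
# HTA committee. Prices in EUR/patient; thousands separators stripped; empty cell = not available.
# Farawave: comparator prices are radiofrequency (3090) and cryoballoon (4090) ablation, mean 3590;
# the documented per-patient saving used in the calculation was 1075 (carried as an override).
# Cardiomems: VBP taken from the published full cost-effectiveness analysis (8475).
# Neovasc: benefit assumed 0.05 QALYs/patient, monetised at the regional 60000 EUR/QALY threshold.
code,name,device_price_eur,comparator_name,comparator_prices_eur,comparator_price_override_eur,endpoint_name,endpoint_direction,rate_new_pct,rate_comparator_pct,stated_improvement_pct,qaly_gain,delta_cost_eur,delta_cost_override_eur,has_comparative_study,has_adequate_comparator,benefit_valuable,external_cea_vbp_eur,procurement_approved,supportive_evidence
276,Flow Triever,8000,Systemic thrombolysis,809,,Composite endpoint of treatment unsuccess,lower_better,17,63.9,73.4,,0,,1,1,1,,1,0
303,Hot Spaxus,5000,Hot Axios,6000,,Severe bleeding requiring transfusion or intervention,lower_better,1.5,6.8,77.9,,0,,1,1,1,,1,0
126,Ekosonic endovascular system,3360,Catheter-directed thrombolysis,363,,Reduction of systolic pulmonary artery pressure,,,,0,,0,,1,1,1,,0,0
307,Circular suturing machine for open surgery,400,Conventional circular staplers,306,,Anastomotic bleeding,lower_better,0.7,5.5,87.3,,0,,1,1,1,,1,0
309,Farawave,5500,Thermal ablation (radiofrequency; cryoballoon),3090;4090,,No improvement in clinical outcomes,,,,0,,,1075,1,1,1,,1,0
301,Intellis Surescan MRI,22600,Traditional spinal cord stimulation,14640,,Low back pain responder rate,higher_better,80.1,51.2,56,,0,,1,1,1,,1,0
289,Urolift,1575,Transurethral resection of the prostate,1351,,BPH6 composite recovery endpoint,higher_better,82,53,57.6,,0,,1,1,1,,1,0
302,Fitostimoline Plus,29.6,Advanced antiseptic dressings followed by hyaluronate gauze,30,,,,,,,,,,0,1,1,,0,0
294,Signia small,1500,Sutures with larger diameter vascular loaders,,,,,,,,,,,0,1,1,,0,0
296,Tricvalve,24000,Not selected,,,,,,,,,,,0,0,1,,0,0
297,Venaseal,620,Radiofrequency ablation (ClosureFast catheters),392,,Freedom from recanalisation at 60 months,higher_better,91.4,85.2,7.3,,0,,1,1,1,,1,0
287,Cardioband Tricuspid,22000,Transcatheter edge-to-edge repair (TriClip/PASCAL/MitraClip),22000,,No difference in clinical outcomes,,,,0,,0,,1,1,1,,1,0
293,Motiva Ergonomix,950,Smooth round silicone gel breast implants,472.5,,Expected reduction in the inflammatory response,,,,,,0,,0,1,1,,1,1
305,Cardiomems,12000,No remote monitoring of the patient,0,,QALYs,,,,,0.1908,1733,,1,1,1,8475,1,0
310,Optilume,2000,Urethroplasty surgery,3059,,Success of the intervention,,,,0,,0,,1,1,1,,1,0
292,Fixnip,900,No other such device available,0,,Reconstruction of the areola-nipple complex,,,,,,,,0,1,0,,0,0
315,Neovasc Reducer,6350,Sham procedure,0,,Quality of life (100-point scale),,,,,0.05,0,,1,1,1,,1,0
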