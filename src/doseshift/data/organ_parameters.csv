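# Thoracic organ radiobiological parameters for the EUD-based logistic
# TCP/NTCP models.  D50 is TCD50 for the target and TD50 for organs at risk
# (conventional fractionation, LKB-derived a = 1/n exponents).
# gamma50 slopes are rarely published alongside EUD limit tables; rows marked
# derived-from-1pct-column carry the slope recovered by inverting the
# tabulated EUD cap at NTCP = 1% (see radbio.derive_gamma50), rounded to the
# nearest integer.  eud_max_* are the EUD caps (Gy) at NTCP <= 1% / 5%.
name,organ_class,d50,a,gamma50,gamma50_provenance,endpoint,eud_max_1pct,eud_max_5pct,dose_limits
Target,target,50,-10,2,assumed-typical-target-slope,Tumor control,,,
Lungs,parallel,24.5,1.2,2,derived-from-1pct-column,Pneumonitis,13.9,17.1,Dmean<15..20
Lungs (heterogeneity-corrected),parallel,30.8,1.01,2,derived-from-1pct-column,Pneumonitis,17.4,21.4,Dmean<15..20
Esophagus,serial,68,18,4,derived-from-1pct-column,Perforation,51.1,56.5,Dmean<34;D2%<69
Esophagus (acute),serial,51,2.27,4,derived-from-1pct-column,Acute esophagitis grade 2-3,38.4,42.4,Dmean<34
Heart,serial,48,3.1,3,derived-from-1pct-column,Pericarditis,32.8,37.5,Dmean<26;D2%<30
Spinal cord,serial,66.5,20,4,derived-from-1pct-column,Necrosis,49.9,55.3,D2%<50
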