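class_id	kind	formula_template	required
PFCA	neutral-loss	CO2	true
PFCA	anion-fragment	C{n-1}F{2n-1}	false
PFSA	anion-fragment	SO3	true
PFSA	anion-fragment	SO2F	false
PFSA	anion-fragment	SO3F	false
PFSA	anion-fragment	C{n}F{2n+1}	false
PFdiOA	neutral-loss	C2HFO4	true
PFdiOA	anion-fragment	C{n-2}F{2n-5}	false
H-PFCA	neutral-loss	CHFO2	true
H-PFSA	anion-fragment	SO3	true
H-PFSA	anion-fragment	SO2F	false
H-PFSA	anion-fragment	SO3F	false
H-PFSA	anion-fragment	C{n}F{2n-1}	false
PFECA	neutral-loss	CO2	true
PFECA	anion-fragment	CF3	false
FTSA	anion-fragment	SO3	true
FTSA	anion-fragment	SO2F	false
FTSA	neutral-loss	HF	false
Cl-PFESA	anion-fragment	SO3	true
Cl-PFESA	anion-fragment	SO2F	false
Cl-PFESA	anion-fragment	C6ClF12O	false
H-PFESA	anion-fragment	SO3	true
H-PFESA	anion-fragment	SO2F	false
H-PFESA	anion-fragment	C2F3O	false
H-PFESA	anion-fragment	C2HF4O	false
PFSM	anion-fragment	SO3	true
PFSM	anion-fragment	SO2F	false
PFSM	anion-fragment	C4HF9NO2S	false
HNTf2	anion-fragment	SO3	true
HNTf2	anion-fragment	SO2F	false
HNTf2	anion-fragment	CF3NO2S	false
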