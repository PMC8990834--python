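product_code,atc_code,name,doses_per_pack,standard_daily_dose,is_controller
FPSAL250,R03AK06,fluticasone propionate/salmeterol 250/25 pMDI,120,4,true
FPSAL125,R03AK06,fluticasone propionate/salmeterol 125/25 pMDI,120,4,true
FPSAL500A,R03AK06,fluticasone propionate/salmeterol 500/50 DPI,60,2,true
BUDFORM200,R03AK07,budesonide/formoterol 200/6 DPI,120,4,true
BUDFORM400,R03AK07,budesonide/formoterol 400/12 DPI,60,2,true
FLUTFORM125,R03AK08,fluticasone propionate/formoterol 125/5 pMDI,120,4,true
BEC100,R03BA01,beclometasone dipropionate 100 pMDI,200,2,true
BUD200,R03BA02,budesonide 200 DPI,200,2,true
FP250,R03BA05,fluticasone propionate 250 pMDI,120,2,true
CIC160,R03BA08,ciclesonide 160 pMDI,120,1,true
SALB100,R03AC02,salbutamol 100 pMDI,200,4,false
TERB500,R03AC03,terbutaline 500 DPI,120,2,false
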