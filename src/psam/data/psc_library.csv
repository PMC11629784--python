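name,compartment,DAPI,Foxp3,pSTAT3,CD45,CD3,CD4,CD8,PD1,ICOS,IgG,CD20-like,CD138-like,CD14-like
generic nucleus,nucleus,1,0,0,0,0,0,0,0,0,0,0,0,0
Foxp3+ nucleus,nucleus,1,1,0,0,0,0,0,0,0,0,0,0,0
pSTAT3+ nucleus,nucleus,1,0,1,0,0,0,0,0,0,0,0,0,0
CD4 T cell,membrane,0,0,0,1,1,1,0,0,0,0,0,0,0
ICOS+ CD4 T cell,membrane,0,0,0,1,1,1,0,0,1,0,0,0,0
exhausted CD4 T cell,membrane,0,0,0,1,1,1,0,1,0,0,0,0,0
CD8 T cell,membrane,0,0,0,1,1,0,1,0,0,0,0,0,0
exhausted CD8 T cell,membrane,0,0,0,1,1,0,1,1,0,0,0,0,0
ICOS+ CD8 T cell,membrane,0,0,0,1,1,0,1,0,1,0,0,0,0
other T cell,membrane,0,0,0,1,1,0,0,0,0,0,0,0,0
B cell,membrane,0,0,0,1,0,0,0,0,0,0,1,0,0
IgG+ B cell,membrane,0,0,0,1,0,0,0,0,0,1,1,0,0
plasma cell,membrane,0,0,0,0.5,0,0,0,0,0,0,0,1,0
IgG+ plasma cell,membrane,0,0,0,0.5,0,0,0,0,0,1,0,1,0
macrophage,membrane,0,0,0,1,0,0,0,0,0,0,0,0,1
other immune cell,membrane,0,0,0,1,0,0,0,0,0,0,0,0,0
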