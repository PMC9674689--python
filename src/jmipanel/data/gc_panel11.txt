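# Published 11-gene gastric-cancer biomarker panel (gene symbols).
STX12
PHF14
ECT2
PRIM2
CENPL
CTHRC1
INHBA
RNFT2
CLSPN
ESM1
COL10A1
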