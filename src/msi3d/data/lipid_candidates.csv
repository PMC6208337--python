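name,formula,adduct
AC(14:0) tetradecanoylcarnitine,C21H41NO4,[M+H]+
AC(16:1) palmitoleoylcarnitine,C23H43NO4,[M+H]+
AC(16:0) palmitoylcarnitine,C23H45NO4,[M+H]+
AC(18:1) elaidic carnitine,C25H47NO4,[M+H]+
lysoPC(16:0),C24H50NO7P,[M+Na]+
lysoPC(18:1),C26H52NO7P,[M+Na]+
lysoPC(18:0),C26H54NO7P,[M+Na]+
heme b,C34H32FeN4O4,[M]+.
PC(16:0/20:4),C44H80NO8P,[M+K]+
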