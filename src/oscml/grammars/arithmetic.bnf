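<expr> ::= <binop>(<expr>, <expr>) | <leaf>
<binop> ::= add | sub | mul | div
<leaf> ::= <var> | <const>
<var> ::= R0 | S | Rm | R4 | R20 | R4_R20 | Xm | Fr | Cdyn | Ax | Z4 | R | Rp | I | C | Rt
<const> ::= 0.<digit>
<digit> ::= 1 | 2 | 3 | 4 | 5 | 6 | 7 | 8 | 9
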