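<expr> ::= <agg> | <mod> | <var>
<agg> ::= max(<expr>, <expr>) | min(<expr>, <expr>) | WA(<expr>, <expr>, <r>) | OWA(<expr>, <expr>, <r>)
<mod> ::= dilator(<expr>) | concentrator(<expr>)
<r> ::= 0.1 | 0.2 | 0.3 | 0.4 | 0.5 | 0.6 | 0.7 | 0.8 | 0.9
<var> ::= R0_low | R0_medium | R0_high | S_low | S_medium | S_high | Rm_low | Rm_medium | Rm_high | R4_low | R4_medium | R4_high | R20_low | R20_medium | R20_high | R4_R20_low | R4_R20_medium | R4_R20_high | Xm_low | Xm_medium | Xm_high | Fr_low | Fr_medium | Fr_high | Cdyn_low | Cdyn_medium | Cdyn_high | Ax_low | Ax_medium | Ax_high | Z4_low | Z4_medium | Z4_high | R_low | R_medium | R_high | Rp_low | Rp_medium | Rp_high | I_low | I_medium | I_high | C_low | C_medium | C_high | Rt_low | Rt_medium | Rt_high
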