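sample_id	group	c_j22p_j23	c_j23	ratio_printed	biomed2
TCL1	TCL	2.6	9.7	26.6	TCRγ: monoclonal; TCRβ: polyclonal
TCL2	TCL	11.5	83.3	13.8	TCRγ: monoclonal; TCRβ: polyclonal
TCL3	TCL	5.0	50.6	10.0	TCRγ: monoclonal; TCRβ: polyclonal
TCL4	TCL	4.9	21.9	22.5	TCRγ: monoclonal; TCRβ: polyclonal
TCL5	TCL	8.2	16.8	48.7	TCRγ: polyclonal; TCRβ: polyclonal
TCL6	TCL	1.0	3.1	31.1	TCRγ: polyclonal; TCRβ: polyclonal
TCL7	TCL	12.7	225.6	5.6	TCRγ: polyclonal; TCRβ: polyclonal
TCL8	TCL	23.0	261.8	8.8	TCRγ: polyclonal; TCRβ: polyclonal
TCL9	TCL	2.6	30.5	8.6	TCRγ: polyclonal; TCRβ: polyclonal
Non-TCL1	non-TCL	8.6	398.0	2.2	N.A.
Non-TCL2	non-TCL	8.2	405.5	2.0	N.A.
Non-TCL3	non-TCL	3.3	158.3	2.1	N.A.
Non-TCL4	non-TCL	33.8	793.8	4.3	N.A.
Non-TCL5	non-TCL	2.6	79.3	3.3	N.A.
Non-TCL6	non-TCL	2.8	80.6	3.6	N.A.
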