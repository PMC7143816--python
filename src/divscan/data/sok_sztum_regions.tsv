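chromosome	start_bp	end_bp	size_bp
2	80426523	80826149	399626
3	19391644	20068977	677333
5	19725673	20099989	374316
6	67856137	68433748	577611
7	61694614	62521051	826437
11	27516665	27795394	278729
13	10773369	11155590	382221
15	34201183	34674868	473685
17	63875241	64221049	345808
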