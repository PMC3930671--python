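species,b0,b1,b2,b3,b4,b5,use_dbh,use_dbh2,use_cr,use_ba,use_hi,provenance
JP,0.50,0.140,-0.00030,1.50,0.000,-0.015,1,1,1,0,1,synthetic default (Jeffrey pine archetype)
WF,0.60,0.120,-0.00025,1.20,-0.010,-0.010,1,1,1,1,1,synthetic default (white fir archetype)
IC,0.70,0.110,-0.00020,1.00,0.000,0.000,1,1,1,0,0,synthetic default (incense cedar archetype)
SP,0.55,0.130,-0.00028,1.40,0.000,-0.012,1,1,1,0,1,synthetic default (sugar pine archetype)
LP,0.45,0.100,-0.00020,1.00,0.000,0.000,1,1,1,0,0,synthetic default (lodgepole pine archetype)
SJ,0.80,0.120,-0.00025,0.00,0.000,0.000,1,1,0,0,0,synthetic default (western juniper archetype)
QA,0.90,0.120,-0.00022,0.00,0.000,0.000,1,1,0,0,0,synthetic default (quaking aspen archetype)
QU,1.00,0.130,-0.00025,0.00,0.000,0.000,1,1,0,0,0,synthetic default (oak archetype)
PE,0.90,0.110,-0.00022,0.00,0.000,0.000,1,1,0,0,0,synthetic default (bitter cherry archetype)
CONIFER_DEFAULT,0.60,0.125,-0.00025,1.20,0.000,0.000,1,1,1,0,0,synthetic genus-level fallback
HARDWOOD_DEFAULT,0.90,0.120,-0.00022,0.00,0.000,0.000,1,1,0,0,0,synthetic genus-level fallback
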