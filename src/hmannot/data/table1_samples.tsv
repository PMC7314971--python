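sample_id	species	property	organ	clade	accession
cold1	Rehmannia glutinosa	Cold	Roots	dicot	SRR832972
cold2	Dracocephalum tanguticum	Cold	Leaves	dicot	SRR2915458
cold3	Scutellaria baicalensis	Cold	Roots	dicot	SRR3367956
cold4	Catharanthus roseus	Cold	Flowers	dicot	SRR1271859
cold5	Andrographis paniculata	Cold	Leaves	dicot	SRR1519324
cold6	Swertia mussotii	Cold	Flowers	dicot	SRR3951703
cold7	Gentiana rigescens	Cold	Roots	dicot	SRR924095
cold8	Gardenia jasminoides	Cold	Petals	dicot	SRR1045129
cold9	Lonicera japonica	Cold	Flowers	dicot	SRR3591711
cold10	Isatis tinctoria	Cold	Leaves	dicot	SRR1565773
hot1	Allium fistulosum	Hot	Leaves	non_dicot	SRR1609976
hot2	Isodon rubescens	Hot	Leaves	dicot	SRR5367856
hot3	Curcuma longa	Hot	Rhizomes	non_dicot	SRR3928562
hot4	Atractylodes lancea	Hot	Rhizomes	dicot	SRR3104394
hot5	Erigeron breviscapus	Hot	Flowers	dicot	SRR1867750
hot6	Ephedra sinica	Hot	Shoot tip	non_dicot	SRR1188607
hot7	Anemone flaccida	Hot	Stems	dicot	SRR3233423
hot8	Pinellia ternata	Hot	Tubers	non_dicot	SRR1186931
hot9	Panax notoginseng	Hot	Roots	dicot	SRR1032053
hot10	Lindera glauca	Hot	Roots	non_dicot	SRR1438496
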