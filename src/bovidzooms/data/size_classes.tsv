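# Bovid body-size classes (Brain's classes 1-4) compatible with each
# panel taxon.  Used only as a constraint filter on candidate sets.
name	size_min	size_max
Bovina	3	4
Bubalina	4	4
Tragelaphini-1	3	4
Tragelaphini-2	2	3
Aepycerotinae	2	2
Antilopini	1	2
Ourebia-Raphicerus	1	1
Neotragus	1	1
Oreotragus	1	1
Madoqua	1	1
Sylvicapra	1	2
Cephalophus	1	2
Philantomba	1	1
Reduncinae	2	3
Hippotraginae	3	3
Alcelaphus	3	3
Connochaetes-Damaliscus	3	3
Pantholopinae	2	2
Capra	1	2
Ovis	1	2
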