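name	subfamily	tribe	group	evidence	members	P1	A	A'	375-386	375-396	375-396'	B	889-906	C	P2	D	E	F	F'	G	G'
Bovina	Bovinae	Bovini	Bovina	MALDI+LCMSMS	Bos taurus,Bos grunniens,Bison bison	1105	1192	1208	1182?	2056?	2072?	1427	1532	1580	1648	2131	2792	2853	2869	3017!	3033
Bubalina	Bovinae	Bovini	Bubalina	MALDI+LCMSMS	Bubalus bubalis,Syncerus caffer	1105	1192	1208	1182?	2056?	2072?	1455	1532	1580	1648	2131	2792	2853	2869	3059	3075
Tragelaphini-1	Bovinae	Tragelaphini	Group 1	MALDI+LCMSMS	Taurotragus oryx,Taurotragus derbianus,Tragelaphus buxtoni,Tragelaphus eurycerus	1105	1192	1208	1182?	2056?	2072?	1427	1560?	1580	1648	2131	2792	2883	2899	3043	3059
Tragelaphini-2	Bovinae	Tragelaphini	Group 2	predicted	Tragelaphus imberbis,Tragelaphus strepsiceros,Tragelaphus scriptus,Tragelaphus spekii	1105	1192	1208	1182?	2056?	2072?	1427	1532	1580	1648	2131	2792	2883	2899	3043	3059
Aepycerotinae	Aepycerotinae	-	-	MALDI+LCMSMS	Aepyceros melampus	1105	1180	1196	1182?	2056?	2072?	1427	1532	1550	1648	2131	2792	2883	2899	3017!	3033
Antilopini	Antilopinae	Antilopini	Nanger-Eudorcas-Antidorcas	MALDI+LCMSMS	Nanger granti,Eudorcas thomsonii,Antidorcas marsupialis	1105	1180	1196	1182?	2056?	2072?	1427	1532	1550	1648	2131	2792	2883	2899	3017!	3033
Ourebia-Raphicerus	Antilopinae	Neotragini	Ourebia-Raphicerus	MALDI+LCMSMS	Ourebia ourebi,Raphicerus campestris	1105	1180	1196	1182?	2056?	2072?	1427	1532	1550	1648	2131	2792	2883	2899	3017!	3033
Neotragus	Antilopinae	Neotragini	Neotragus	MALDI+LCMSMS	Neotragus moschatus	1105	1180	1196	1182?	2056?	2072?	1427	1532	1580	1648	2131	2792	2883	2899	3017!	3033
Oreotragus	Antilopinae	Neotragini	Oreotragus	MALDI+LCMSMS	Oreotragus oreotragus	1105	1192	1208	1154	2028	2044	1427	1532	1580	1648	2131	2792	2883	2899	3017!	3033
Madoqua	Antilopinae	Neotragini	Madoqua	MALDI+LCMSMS	Madoqua kirkii	1105	1166	1182	1182?	2056?	2072?	1427	1532	1550	1648	2131	2792	2883	2899	3017!	3033
Sylvicapra	Cephalophinae	-	Sylvicapra	MALDI+LCMSMS	Sylvicapra grimmia	1105	1192	1208	1182?	2056?	2072?	1427	1532	1580	1648	2131	2792	2853	2869	3043	3059
Cephalophus	Cephalophinae	-	Cephalophus	MALDI+LCMSMS	Cephalophus harveyi,Cephalophus adersi	1105	1192	1208	1154	2028	2044	1427	1574	1580	1648	2131	2792	2853	2869	3043	3059
Philantomba	Cephalophinae	-	Philantomba	predicted	Philantomba maxwellii	1105	1192	1208	1154	2028	2044	1427	1560?	1580	1648	2131	2792	2883	2899	3043	3059
Reduncinae	Reduncinae	-	-	MALDI+LCMSMS	Kobus kob,Kobus ellipsiprymnus,Redunca redunca	1105	1150	1166	1182?	2056?	2072?	1427	1532	1550	1648	2131	2792	2883	2899	3017!	3033
Hippotraginae	Hippotraginae	-	-	MALDI+LCMSMS	Hippotragus niger,Hippotragus equinus,Oryx gazella	1105	1180	1196	1154	2028	2044	1427	1588	1580	1648	2131	2792	2883	2899	3043	3059
Alcelaphus	Alcelaphinae	-	Alcelaphus	MALDI+LCMSMS	Alcelaphus buselaphus	1105	1180	1196	1154	2028	2044	1427	1590	1550	1648	2131	2792	2883	2899	3017!	3033
Connochaetes-Damaliscus	Alcelaphinae	-	Connochaetes-Damaliscus	MALDI+LCMSMS	Connochaetes taurinus,Damaliscus lunatus,Damaliscus hunteri	1105	1180	1196	1154	2028	2044	1427	1560?	1550	1648	2131	2792	2883	2899	3017!	3033
Pantholopinae	Pantholopinae	-	-	predicted	Pantholops hodgsonii	1105	1180	1196	1182?	2056?	2072?	1427	1560?	1580	1648	2131	2792	2857	2873	3017!	3033
Capra	Caprinae	-	Capra	MALDI+LCMSMS	Capra hircus,Capra ibex	1105	1180	1196	1154	2028	2044	1427	1560?	1580	1648	2131	2792	2883	2899	3077	3093
Ovis	Caprinae	-	Ovis	MALDI+LCMSMS	Ovis aries	1105	1180	1196	1154	2028	2044	1427	1560?	1580	1648	2131	2792	2883	2899	3017!	3033
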