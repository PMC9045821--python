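# synthetic stand-in annotation: published site positions kept, fill-in positions synthetic
contig	position	canonical	mod_code	guide
18S	100	A	Am	snR51
18S	106	U	Y	snR44
18S	123	U	Y	
18S	292	U	Y	
18S	302	A	Am	
18S	320	U	Y	
18S	351	A	Am	
18S	436	A	Am	snR87
18S	526	C	Cm	
18S	562	U	Y	
18S	632	U	Y	snR161
18S	759	U	Y	snR80
18S	766	U	Y	snR161
18S	785	U	Y	
18S	835	U	Um	
18S	870	U	Y	
18S	974	A	Am	snR54
18S	999	U	Y	snR31
18S	1037	C	Cm	
18S	1045	U	Y	
18S	1191	U	m1acp3Y	snR35
18S	1243	A	Am	
18S	1269	U	Um	snR55
18S	1271	G	Gm	snR41
18S	1280	C	ac4C	snR4
18S	1290	U	Y	snR83
18S	1313	G	Gm	
18S	1415	U	Y	snR83
18S	1449	U	Y	
18S	1481	U	Um	
18S	1556	G	Gm	
18S	1639	C	Cm	snR70
18S	1700	U	Y	
18S	1722	U	Y	
18S	1738	U	Y	
18S	1773	C	ac4C	snR45
18S	1782	A	m62A	Dim1
25S	65	C	Cm	
25S	153	U	Y	
25S	252	A	Am	
25S	361	U	Y	
25S	368	A	Am	
25S	442	U	Y	
25S	469	A	Am	
25S	512	U	Y	
25S	535	U	Y	
25S	543	G	Gm	
25S	561	U	Y	
25S	640	C	Cm	
25S	672	U	Y	
25S	678	U	Y	
25S	787	U	Y	
25S	817	A	Am	snR60
25S	846	A	Am	
25S	902	U	Y	
25S	908	G	Gm	snR60
25S	916	U	Y	
25S	972	G	Gm	
25S	1097	U	Y	
25S	1106	U	Y	
25S	1131	U	Y	
25S	1145	A	Am	
25S	1237	G	Gm	
25S	1249	C	Cm	
25S	1323	U	Y	
25S	1339	C	Cm	
25S	1380	U	Y	
25S	1410	U	Y	
25S	1431	C	Cm	
25S	1437	C	Cm	U24
25S	1449	A	Am	U24
25S	1450	G	Gm	U24
25S	1473	U	Um	
25S	1500	U	Um	
25S	1645	U	Y	
25S	1654	A	Am	
25S	1729	U	Um	
25S	1786	U	Y	
25S	1854	U	Y	
25S	1867	U	Um	
25S	1907	U	Y	
25S	1923	A	Am	
25S	1947	G	Gm	
25S	1979	A	Am	
25S	2093	C	Cm	
25S	2162	U	Y	
25S	2202	U	Y	
25S	2284	G	Gm	
25S	2464	U	Um	
25S	2484	U	Y	
25S	2619	G	Gm	snR67
25S	2627	C	Cm	
25S	2639	G	Gm	
25S	2671	U	Y	
25S	2724	U	Um	snR67
25S	2748	G	Gm	
25S	2756	U	Um	
25S	2789	U	Um	
25S	2846	U	Y	
25S	2906	U	Y	
25S	2921	U	Um	snR52
25S	2922	G	Gm	Spb1
25S	2923	U	Y	snR10
25S	3018	U	Y	
25S	3102	C	Cm	
25S	3120	U	Y	
25S	3154	U	Um	
25S	3160	G	Gm	
25S	3227	U	Y	
25S	3330	U	Y	
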