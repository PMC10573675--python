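case_id,observer_id,median_mm3,q1_mm3,q3_mm3,raw
1,junior,1720,1675,1787,"1720 (1675–1787)"
1,senior,1664,1645,1691,"1664 (1645–1691)"
1,expert,1609,1598,1680,"1609 (1598–1680)"
2,junior,1210,1177,1216,"1210 (1177–1216)"
2,senior,1209,1196,1239,"1209 (1196–1239)"
2,expert,1165,1155,1191,"1165 (1155–1191)"
3,junior,92,92,96,"92 (92–96)"
3,senior,63.16,59.31,63.63,"63.16 (59.31–63.63)"
3,expert,83,82,90,"83 (82–90)"
4,junior,681,672,684,"681 (672–684)"
4,senior,636.5,632.8,642,"636.5 (632.8–642)"
4,expert,706,630,710,"706 (630–710)"
5,junior,255,249,265,"255 (249–265)"
5,senior,314.4,312.1,320.5,"314.4 (312.1–320,5)"
5,expert,244,225,248,"244 (225–248)"
6,junior,154,141,159,"154 (141–159)"
6,senior,169.9,161,170.8,"169.9 (161–170.8)"
6,expert,121,119,178,"121 (119–178)"
7,junior,2184,2154,2198,"2184 (2154–2198)"
7,senior,1857,1817,1970,"1857 (1817–1970)"
7,expert,2049,2023,2049,"2049 (2023–2049)"
8,junior,190,190,196,"190 (190–196)"
8,senior,204,201,211,"204 (201–211)"
8,expert,178,165,181,"178 (165–181)"
9,junior,648,640,654,"648 (640–654)"
9,senior,604,571.7,617.8,"604 (571.7–617.8)"
9,expert,664,640,680,"664 (640–680)"
10,junior,472,468,493,"472 (468–493)"
10,senior,424.1,422.6,468,"424.1 (422.6–468)"
10,expert,530,528,547,"530 (528–547)"
11,junior,1605,1557,1610,"1605 (1557–1610)"
11,senior,1643,1600,1660,"1643 (1600–1660)"
11,expert,1649,1616,1706,"1649 (1616–1706)"
12,junior,7404,7311,7567,"7404 (7311–7567)"
12,senior,7238,7100,7360,"7238 (7100–7360)"
12,expert,6423,6423,6679,"6423 (6423–6679)"
13,junior,7040,6582,7047,"7040 (6582–7047)"
13,senior,6844,6815,6896,"6844 (6815–6896)"
13,expert,7156,7003,7178,"7156 (7003–7178)"
14,junior,1903,1900,1926,"1903 (1900–1926)"
14,senior,3414,3345,3518,"3414 (3345–3518)"
14,expert,2391,2377,2408,"2391 (2377–2408)"
15,junior,987,984,1034,"987 (984–1034)"
15,senior,988,921,994,"988 (921–994)"
15,expert,856,824,856,"856 (824–856)"
16,junior,3114,3059,3132,"3114 (3059–3132)"
16,senior,2988,2921,2994,"2988 (2921–2994)"
16,expert,3132,3132,3154,"3132 (3132–3154)"
17,junior,177,168,183,"177 (168–183)"
17,senior,176,175,178,"176 (175–178)"
17,expert,120,112,120,"120 (112–120)"
18,junior,312,308,339,"312 (308–339)"
18,senior,315,314,319,"315 (314–319)"
18,expert,215,213,242,"215 (213–242)"
19,junior,1913,1905,1980,"1913 (1905–1980)"
19,senior,2161,2129,2203,"2161 (2129–2203)"
19,expert,1440,1440,1440,"1440 (1440–1440)"
20,junior,92,83,96,"92 (83–96)"
20,senior,82,81,82,"82 (81–82)"
20,expert,80,77,84,"80 (77–84)"
21,junior,2180,2173,2218,"2180 (2173–2218)"
21,senior,1942,1887,1983,"1942 (1887–1983)"
21,expert,2057,2048,2059,"2057 (2048–2059)"
22,junior,983,932,1009,"983 (932–1009)"
22,senior,613,565,624,"613 (565–624)"
22,expert,1006,2048,2059,"1006 (2048–2059)"
23,junior,3371,3313,3469,"3371 (3313–3469)"
23,senior,3731,3731,3811,"3731 (3731–3811)"
23,expert,4178,4178,4178,"4178 (4178–4178)"
24,junior,31,30,33,"31 (30–33)"
24,senior,26,25,27,"26 (25–27)"
24,expert,34,25,34,"34 (25–34)"
25,junior,4016,3990,4017,"4016 (3990–4017)"
25,senior,3047,3024,3052,"3047 (3024–3052)"
25,expert,4276,4276,4276,"4276 (4276–4276)"
26,junior,9518,9449,9521,"9518 (9449–9521)"
26,senior,9247,9167,9263,"9247 (9167–9263)"
26,expert,9446,9430,9459,"9446 (9430–9459)"
27,junior,901,897,948,"901 (897–948)"
27,senior,858,828,864,"858 (828–864)"
27,expert,886,886,886,"886 (886–886)"
28,junior,375,399,399,"375 (399–399)"
28,senior,343,339,351,"343 (339–351)"
28,expert,442,395,444,"442 (395–444)"
29,junior,385,384,399,"385 (384–399)"
29,senior,356,340,357,"356 (340–357)"
29,expert,211,211,211,"211 (211–211)"
30,junior,499,485,503,"499 (485–503)"
30,senior,495,482,498,"495 (482–498)"
30,expert,463,463,497,"463 (463–497)"
31,junior,4257,4239,4265,"4257 (4239–4265)"
31,senior,4105,4028,4106,"4105 (4028–4106)"
31,expert,3830,3581,4063,"3830 (3581–4063)"
32,junior,128,126,134,"128 (126–134)"
32,senior,123,121,125,"123 (121–125)"
32,expert,162,161,162,"162 (161–162)"
33,junior,5733,5681,5740,"5733 (5681–5740)"
33,senior,5352,5305,5366,"5352 (5305–5366)"
33,expert,5823,5822,5826,"5823 (5822–5826)"
34,junior,1378,1354,1399,"1378 (1354–1399)"
34,senior,1312,1312,1332,"1312 (1312–1332)"
34,expert,1497,1497,1504,"1497 (1497–1504)"
35,junior,346,313,355,"346 (313–355)"
35,senior,216,216,224,"216 (216–224)"
35,expert,261,261,261,"261 (261–261)"
36,junior,1393,1235,1696,"1393 (1235–1696)"
36,senior,756,755,758,"756 (755–758)"
36,expert,1352,1346,1372,"1352 (1346–1372)"
37,junior,873,808,880,"873 (808–880)"
37,senior,604,599,627,"604 (599–627)"
37,expert,510,489,550,"510 (489–550)"
38,junior,252,241,254,"252 (241–254)"
38,senior,226,224,228,"226 (224–228)"
38,expert,254,250,260,"254 (250–260)"
39,junior,297,288,301,"297 (288–301)"
39,senior,294,277,323,"294 (277–323)"
39,expert,361,361,362,"361 (361–362)"
40,junior,9485,9473,9499,"9485 (9473–9499)"
40,senior,9021,8707,9069,"9021 (8707–9069)"
40,expert,9212,9212,9212,"9212 (9212–9212)"
41,junior,10606,10337,10624,"10,606 (10,337–10,624)"
41,senior,9982,9924,10011,"9982 (9924–10,011)"
41,expert,11652,11652,11652,"11,652 (11,652–11,652)"
42,junior,3805,3723,3892,"3805 (3723–3892)"
42,senior,4015,4007,4136,"4015 (4007–4136)"
42,expert,4581,4581,4756,"4581 (4581–4756)"
43,junior,249,230,276,"249 (230–276)"
43,senior,152,145,159,"152 (145–159)"
43,expert,234,231,240,"234 (231–240)"
44,junior,266,263,271,"266 (263–271)"
44,senior,240,234,241,"240 (234–241)"
44,expert,273,269,284,"273 (269–284)"
45,junior,1567,1460,1786,"1567 (1460–1786)"
45,senior,1621,1494,1660,"1621 (1494–1660)"
45,expert,1512,1470,1514,"1512 (1470–1514)"
46,junior,1187,1037,1233,"1187 (1037–1233)"
46,senior,1042,1019,1076,"1042 (1019–1076)"
46,expert,1234,1208,1234,"1234 (1208–1234)"
47,junior,2172,2169,2200,"2172 (2169–2200)"
47,senior,2033,1019,1076,"2033 (1019–1076)"
47,expert,2343,2300,2412,"2343 (2300–2412)"
48,junior,3671,3660,3690,"3671 (3660–3690)"
48,senior,3464,3448,3493,"3464 (3448–3493)"
48,expert,3897,3578,4001,"3897 (3578–4001)"
49,junior,10621,10599,10647,"10,621 (10,599–10,647)"
49,senior,9858,9849,9916,"9858 (9849–9916)"
49,expert,10717,10717,10717,"10,717 (10,717–10,717)"
50,junior,593,559,598,"593 (559–598)"
50,senior,470,461,485,"470 (461–485)"
50,expert,530,524,532,"530 (524–532)"
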