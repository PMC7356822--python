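quantity,concentration_mM,reference,syn_1_1,syn_1_2,syn_1_3,syn_1_4,syn_1_5,syn_1_6,syn_1_7,syn_2_1,syn_2_2,syn_2_3,syn_2_4,syn_2_5,syn_2_6,syn_2_7
T1,1.0,1131.5,1123.1,1128.8,1122.6,1127.7,1122.2,1119.9,1126.2,1110.5,1111.0,1111.1,1105.6,1107.5,1111.2,1107.8
T1,0.8,1357.8,1254.1,1254.9,1257.5,1260.1,1252.1,1262.0,1257.9,1240.8,1241.3,1231.0,1231.7,1236.6,1235.1,1233.9
T1,0.7,1456.4,1463.0,1474.8,1476.3,1470.0,1460.8,1468.6,1457.3,1419.8,1416.0,1411.2,1402.4,1412.8,1407.9,1404.4
T1,0.6,1503.7,1785.4,1798.6,1794.5,1790.5,1787.7,1781.8,1793.0,1789.3,1776.9,1767.5,1764.9,1771.9,1772.5,1764.5
T1,0.5,1719.0,1883.3,1892.6,1889.5,1885.2,1879.7,1874.3,1898.2,1887.6,1884.6,1872.3,1887.2,1897.6,1888.2,1885.8
T1,0.4,1843.8,2071.6,2088.3,2086.3,2082.1,2077.3,2061.3,2084.3,2099.5,2095.6,2088.2,2096.7,2101.7,2099.8,2100.5
T1,0.2,2117.2,2612.3,2621.5,2620.8,2620.0,2614.7,2610.0,2628.2,2663.2,2665.0,2662.4,2665.8,2669.1,2666.3,2671.7
T2,20.0,58.5,57.4,57.5,57.5,57.5,57.4,57.4,56.9,57.4,57.5,57.5,57.5,57.4,57.4,57.2
T2,15.0,64.0,58.9,58.9,58.9,58.9,58.9,58.9,58.7,58.9,58.9,58.9,58.9,58.9,58.9,58.7
T2,13.0,82.4,80.5,80.6,80.1,80.1,79.7,79.7,80.2,80.5,80.6,80.1,80.1,79.7,79.7,79.9
T2,11.0,94.0,86.4,86.6,86.6,86.2,86.7,86.7,86.8,86.4,86.6,86.6,86.2,86.7,86.7,86.5
T2,9.0,126.7,100.8,100.7,100.7,100.7,100.8,100.8,100.8,100.8,100.7,100.7,100.7,100.8,100.8,100.7
T2,7.0,166.9,122.9,122.4,122.4,122.4,122.2,122.2,122.3,122.9,122.4,122.4,122.4,122.2,122.2,122.4
T2,5.0,230.3,253.3,252.7,253.2,252.2,252.8,252.8,253.1,253.2,252.5,253.1,252.1,252.7,252.7,251.3
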