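period,a,first_diff,sign,ln_m0,r2
1751–1754,0.0625,,x,-7.17,0.9809
1755–1759,0.0619,-0.0006,N,-6.93,0.9845
1760–1764,0.0609,-0.0009,N,-6.88,0.9806
1765–1769,0.064,0.0031,,-7.12,0.9838
1770–1774,0.0589,-0.0051,N,-6.52,0.9832
1775–1779,0.0685,0.0096,,-7.47,0.9859
1780–1784,0.0692,0.0006,,-7.44,0.9842
1785–1789,0.0659,-0.0033,N,-7.13,0.9857
1790–1794,0.0687,0.0028,,-7.37,0.9871
1795–1799,0.0705,0.0018,,-7.49,0.9876
1800–1804,0.0695,-0.0009,N,-7.36,0.9919
1805–1809,0.0653,-0.0042,N,-6.96,0.9946
1810–1814,0.065,-0.0002,N,-6.96,0.9933
1815–1819,0.067,0.002,,-7.26,0.9895
1820–1824,0.0676,0.0005,,-7.33,0.9906
1825–1829,0.0675,-0.0001,N,-7.21,0.9892
1830–1834,0.0677,0.0001,,-7.2,0.9895
1835–1839,0.0708,0.0031,,-7.45,0.9874
1840–1844,0.0708,-0.0001,N,-7.53,0.9891
1845–1849,0.0733,0.0025,,-7.66,0.9889
1850–1854,0.0714,-0.0019,N,-7.54,0.9858
1855–1859,0.0716,0.0001,,-7.61,0.9888
1860–1864,0.0751,0.0035,,-7.98,0.9921
1865–1869,0.0746,-0.0005,N,-7.88,0.9908
1870–1874,0.0745,-0.0001,N,-7.96,0.9883
1875–1879,0.0768,0.0023,,-8.2,0.9863
1880–1884,0.0779,0.0011,,-8.31,0.9858
1885–1889,0.079,0.0011,,-8.44,0.9831
1890–1894,0.0803,0.0013,,-8.5,0.9835
1895–1899,0.0809,0.0006,,-8.62,0.98
1900–1904,0.0805,-0.0003,N,-8.6,0.9805
1905–1909,0.0805,0.0001,,-8.64,0.9809
1910–1914,0.0817,0.0011,,-8.74,0.9837
1915–1919,0.0807,-0.001,N,-8.65,0.9809
1920–1924,0.0849,0.0042,,-9.04,0.9878
1925–1929,0.0856,0.0006,,-9.08,0.9903
1930–1934,0.0875,0.0019,,-9.23,0.9925
1935–1939,0.0901,0.0026,,-9.4,0.9944
1940–1944,0.0926,0.0025,,-9.68,0.9961
1945–1949,0.0964,0.0038,,-9.98,0.9981
1950–1954,0.1002,0.0038,,-10.32,0.9989
1955–1959,0.1016,0.0014,,-10.49,0.9991
1960–1964,0.1026,0.001,,-10.6,0.9992
1965–1969,0.1009,-0.0016,N,-10.51,0.9986
1970–1974,0.098,-0.0029,N,-10.37,0.9987
1975–1979,0.0972,-0.0008,N,-10.33,0.9986
1980–1984,0.0981,0.0009,,-10.47,0.9991
1985–1989,0.0997,0.0015,,-10.65,0.999
1990–1994,0.1007,0.001,,-10.8,0.9986
1995–1999,0.1026,0.0019,,-11.03,0.9983
2000–2004,0.1044,0.0018,,-11.24,0.9978
2005–2009,0.1057,0.0013,,-11.42,0.9972
2010–2014,0.1077,0.002,,-11.66,0.9972
2015–2019,0.1088,0.001,,-11.83,0.9965
2020–2023,0.1102,0.0014,,-11.97,0.9966
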