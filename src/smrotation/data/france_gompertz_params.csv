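period,a,first_diff,sign,ln_m0,r2
1815–1819,0.0648,,x,-7.23,0.9887
1820–1824,0.0672,0.0024,,-7.45,0.9883
1825–1829,0.0674,0.0002,,-7.42,0.99
1830–1834,0.0666,-0.0007,N,-7.32,0.9877
1835–1839,0.0686,0.0019,,-7.49,0.9873
1840–1844,0.0699,0.0013,,-7.61,0.9833
1845–1849,0.0695,-0.0003,N,-7.52,0.9858
1850–1854,0.0715,0.0019,,-7.66,0.9884
1855–1859,0.0727,0.0012,,-7.72,0.9884
1860–1864,0.0734,0.0007,,-7.85,0.9899
1865–1869,0.0723,-0.0011,N,-7.72,0.9886
1870–1874,0.0703,-0.002,N,-7.53,0.9838
1875–1879,0.0746,0.0043,,-7.91,0.9885
1880–1884,0.0732,-0.0014,N,-7.83,0.987
1885–1889,0.0734,0.0002,,-7.86,0.9865
1890–1894,0.0769,0.0034,,-8.02,0.9874
1895–1899,0.0768,-0.0001,N,-8.08,0.9872
1900–1904,0.0768,0.0001,N,-8.06,0.9881
1905–1909,0.0769,0.0001,,-8.05,0.9897
1910–1914,0.0768,-0.0001,N,-8.09,0.9872
1915–1919,0.0743,-0.0024,N,-7.87,0.9723
1920–1924,0.0795,0.0052,,-8.37,0.992
1925–1929,0.0806,0.0011,,-8.42,0.9913
1930–1934,0.0796,-0.001,N,-8.42,0.9932
1935–1939,0.0796,0.0001,,-8.44,0.9936
1940–1944,0.0801,0.0005,,-8.37,0.9844
1945–1949,0.0866,0.0064,,-9.13,0.9951
1950–1954,0.0888,0.0022,,-9.33,0.997
1955–1959,0.0902,0.0014,,-9.51,0.9978
1960–1964,0.0909,0.0006,,-9.62,0.9983
1965–1969,0.0896,-0.0013,N,-9.57,0.9987
1970–1974,0.0894,-0.0002,N,-9.61,0.9978
1975–1979,0.0889,-0.0004,N,-9.65,0.9966
1980–1984,0.09,0.001,,-9.8,0.9952
1985–1989,0.0899,-0.0001,N,-9.9,0.9944
1990–1994,0.0889,-0.0009,N,-9.94,0.9918
1995–1999,0.0892,0.0002,,-10.03,0.9905
2000–2004,0.0892,0.0001,,-10.12,0.9872
2005–2009,0.0894,0.0001,,-10.24,0.9863
2010–2014,0.0904,0.001,,-10.41,0.9866
2015–2019,0.0922,0.0018,,-10.6,0.9882
2020–2023,0.094,0.0018,,-10.71,0.9913
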