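year,catch
1901,0.0
1902,0.0
1903,0.0
1904,212.5
1905,425.0
1906,637.5
1907,850.0
1908,1062.5
1909,1275.0
1910,1275.0
1911,1275.0
1912,1275.0
1913,1275.0
1914,1275.0
1915,1275.0
1916,1249.5
1917,1224.0
1918,1198.5
1919,1173.0
1920,1147.5
1921,1122.0
1922,1096.5
1923,1071.0
1924,1045.5
1925,1020.0
1926,994.5
1927,969.0
1928,943.5
1929,918.0
1930,892.5
1931,867.0
1932,841.5
1933,816.0
1934,790.5
1935,765.0
1936,739.5
1937,714.0
1938,688.5
1939,663.0
1940,637.5
1941,612.0
1942,586.5
1943,561.0
1944,535.5
1945,510.0
1946,484.5
1947,459.0
1948,433.5
1949,408.0
1950,382.5
1951,357.0
1952,331.5
1953,306.0
1954,280.5
1955,255.0
1956,229.5
1957,204.0
1958,178.5
1959,153.0
1960,127.5
1961,102.0
1962,76.5
1963,51.0
1964,25.5
1965,0.0
1966,0.0
1967,0.0
1968,0.0
1969,0.0
1970,0.0
1971,0.0
1972,0.0
1973,0.0
1974,0.0
1975,0.0
1976,0.0
1977,0.0
1978,0.0
1979,0.0
1980,0.0
1981,0.0
1982,0.0
1983,0.0
1984,0.0
1985,0.0
1986,0.0
1987,0.0
1988,0.0
1989,0.0
1990,0.0
1991,0.0
1992,0.0
1993,0.0
1994,0.0
1995,0.0
1996,0.0
1997,0.0
1998,0.0
1999,0.0
2000,0.0
2001,0.0
2002,0.0
2003,0.0
2004,0.0
2005,0.0
2006,0.0
2007,0.0
2008,0.0
2009,0.0
2010,0.0
2011,0.0
2012,0.0
2013,0.0
2014,0.0
2015,0.0
2016,0.0
2017,0.0
2018,0.0
2019,0.0
2020,0.0
2021,0.0
2022,0.0
2023,0.0
2024,0.0
2025,0.0
2026,0.0
2027,0.0
2028,0.0
2029,0.0
2030,0.0
2031,0.0
2032,0.0
2033,0.0
2034,0.0
2035,0.0
2036,0.0
2037,0.0
2038,0.0
2039,0.0
2040,0.0
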